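"""MGIDI selection per regime and cross-regime overlap.

Runs the index chain on the BLUP tables from step 02: rescaling to 0-100,
exploratory factor analysis with varimax rotation, factor scores for the
genotypes and the ideotype, MGIDI ranking, 15%-intensity selection,
strengths/weaknesses shares and per-trait selection gains; finally the
tabular Venn of selections across regimes.  Writes loadings, index, omega
and gains tables plus overlap.json under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from metsel import (BlupTable, compute_mgidi, cross_regime_overlap,
                    default_trait_specs, factor_scores, fit_efa,
                    rescale_traits, select_genotypes, selection_gains,
                    strengths_weaknesses)

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    specs = default_trait_specs()
    selections = {}
    for regime in ("optimal", "drought", "waterlogging"):
        path = os.path.join(RESULTS, f"blups_{regime}.csv")
        if not os.path.exists(path):
            sys.exit("run 02_variance_components.py first")
        bt = BlupTable(values=pd.read_csv(path, index_col=0), regime=regime)
        rt = rescale_traits(bt, specs)
        fm = fit_efa(rt)
        st = factor_scores(rt, fm)
        mr = select_genotypes(compute_mgidi(st), 0.15)
        mr = strengths_weaknesses(st, mr)
        gains = selection_gains(bt, mr.selected, fm, specs)

        fm.loadings.to_csv(os.path.join(RESULTS, f"loadings_{regime}.csv"))
        pd.DataFrame({"MGIDI": mr.mgidi, "rank": mr.ranks,
                      "selected": mr.mgidi.index.isin(mr.selected)}
                     ).to_csv(os.path.join(RESULTS, f"mgidi_{regime}.csv"))
        mr.omega.to_csv(os.path.join(RESULTS, f"omega_{regime}.csv"))
        pd.DataFrame([vars(g) for g in gains]).to_csv(
            os.path.join(RESULTS, f"gains_{regime}.csv"), index=False)
        selections[regime] = mr.selected
        gy = [g for g in gains if g.trait == "GY"][0]
        print(f"{regime}: {fm.n_factors} factors "
              f"({fm.cumulative_pct[fm.n_factors-1]:.1f}% cumulative), "
              f"selected {len(mr.selected)}; GY gain {gy.sd_pct:+.1f}%")
    overlap = cross_regime_overlap(selections)
    with open(os.path.join(RESULTS, "overlap.json"), "w") as fh:
        json.dump(overlap, fh, indent=1, sort_keys=True)
    print(f"common to all regimes: {overlap['all']['members']} "
          f"(n={overlap['all']['count']})")


if __name__ == "__main__":
    main()
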