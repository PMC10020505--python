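"""Per-regime, per-trait mixed models on the simulated trial.

For each soil-moisture regime: EM-REML variance components, likelihood-ratio
tests for the genotype and genotype-x-environment terms, genetic parameters
(h2mg, selection accuracy, R2ge, CVg/CVr) and the two-way BLUP table feeding
the selection index.  Writes results/variance_components.csv and
results/blups_<regime>.csv.
"""

import os
import sys
import warnings

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from metsel import (blup_table, default_trait_specs, fit_trait_model,
                    genetic_parameters, lrt_random_term, read_met_table,
                    subset_regime)

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
PHENO = os.path.join(RESULTS, "synthetic", "phenotypes.csv")


def main():
    if not os.path.exists(PHENO):
        sys.exit("run 01_simulate_trials.py first")
    warnings.filterwarnings("ignore")
    ds = read_met_table(PHENO, default_trait_specs())
    rows = []
    for regime in ("optimal", "drought", "waterlogging"):
        sub = subset_regime(ds, regime)
        fits = {}
        for trait in sub.trait_names:
            fit = fit_trait_model(sub, trait)
            fits[trait] = fit
            gp = genetic_parameters(fit.vc, sub, trait, fit)
            lg = lrt_random_term(sub, trait, "genotype", full=fit)
            lge = lrt_random_term(sub, trait, "gei", full=fit)
            rows.append(dict(
                regime=regime, trait=trait,
                lrt_g=lg.statistic, p_g=lg.p_value,
                lrt_ge=lge.statistic, p_ge=lge.p_value,
                sigma2_g=fit.vc.sigma2_g, sigma2_ge=fit.vc.sigma2_ge,
                sigma2_e=fit.vc.sigma2_e, sigma2_p=fit.vc.sigma2_p,
                r2ge=gp.r2ge, h2mg=gp.h2mg, accuracy=gp.accuracy,
                env_f=gp.env_f, cv_g=gp.cv_g, cv_r=gp.cv_r,
                cv_ratio=gp.cv_ratio, converged=fit.converged))
        bt = blup_table(fits, sub)
        bt.values.to_csv(os.path.join(RESULTS, f"blups_{regime}.csv"))
        hi = max((r for r in rows if r["regime"] == regime),
                 key=lambda r: r["h2mg"])
        print(f"{regime}: highest h2mg {hi['h2mg']:.2f} ({hi['trait']}); "
              f"GY h2mg "
              f"{[r for r in rows if r['regime'] == regime and r['trait'] == 'GY'][0]['h2mg']:.2f}")
    out = pd.DataFrame(rows)
    out.to_csv(os.path.join(RESULTS, "variance_components.csv"), index=False)
    print(f"wrote {os.path.join(os.path.abspath(RESULTS), 'variance_components.csv')}")


if __name__ == "__main__":
    main()
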