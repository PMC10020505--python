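"""Genetic correlations among traits, per regime.

Pearson correlations of BLUP-based predicted genotype means, plus a
hierarchical clustering of traits on 1 - |r| (the tabular stand-in for
correlation network plots).  Writes results/correlations_<regime>.csv and an
edge list for external network drawing.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from metsel import BlupTable, correlation_clusters, genetic_correlations

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    for regime in ("optimal", "drought", "waterlogging"):
        path = os.path.join(RESULTS, f"blups_{regime}.csv")
        if not os.path.exists(path):
            sys.exit("run 02_variance_components.py first")
        blups = BlupTable(values=pd.read_csv(path, index_col=0), regime=regime)
        cm = genetic_correlations(blups)
        cm.r.to_csv(os.path.join(RESULTS, f"correlations_{regime}.csv"))
        cm.edge_list().to_csv(
            os.path.join(RESULTS, f"correlation_edges_{regime}.csv"),
            index=False)
        order, groups = correlation_clusters(cm, height=0.6)
        print(f"{regime}: r(GY, PH) = {cm.r.loc['GY', 'PH']:+.2f}; "
              f"trait groups at cut 0.6: "
              + " | ".join(",".join(g) for g in groups))


if __name__ == "__main__":
    main()
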