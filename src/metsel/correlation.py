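"""Genetic correlations among traits within a soil-moisture regime.

The genetic correlation between two traits is estimated as the Pearson
correlation of their BLUP-based predicted genotype means (a raw
genotype-mean option is available).  A hierarchical clustering on the
distance 1 - |r| provides a tabular stand-in for correlation network plots:
traits that cluster together are the ones a network drawing would place in
proximity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import METDataset, MetDataError
from .mixed import BlupTable

__all__ = ["CorrelationMatrix", "genetic_correlations", "correlation_clusters"]


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    regime: str
    n_genotypes: int

    def edge_list(self) -> pd.DataFrame:
        """Long (trait_a, trait_b, r) table for external network drawing."""
        rows = []
        traits = list(self.r.index)
        for i, a in enumerate(traits):
            for b in traits[i + 1:]:
                rows.append((a, b, self.r.loc[a, b]))
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r"])


def genetic_correlations(blups: BlupTable | None = None, *,
                         ds: METDataset | None = None,
                         use_raw_means: bool = False) -> CorrelationMatrix:
    """Trait-by-trait Pearson correlation of predicted genotype means.

    Pass a ``BlupTable`` (default route), or ``ds`` with
    ``use_raw_means=True`` to correlate raw across-environment genotype means
    instead.  A constant trait column yields missing correlations for its
    pairs (reported as NaN).
    """
    if use_raw_means:
        if ds is None:
            raise MetDataError("use_raw_means requires the dataset")
        tbl = ds.table.groupby("genotype")[ds.trait_names].mean()
        regime = ds.table["regime"].iloc[0] if ds.table["regime"].nunique() == 1 else "mixed"
    else:
        if blups is None:
            raise MetDataError("either a BlupTable or ds with use_raw_means")
        tbl = blups.values
        regime = blups.regime
    if tbl.shape[0] < 3:
        raise MetDataError("need at least 3 genotypes to correlate traits")
    if tbl.shape[1] < 2:
        raise MetDataError("need at least 2 traits")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = tbl.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(r=r, regime=regime, n_genotypes=tbl.shape[0])


def correlation_clusters(cm: CorrelationMatrix, height: float = 0.5
                         ) -> tuple[list[str], list[list[str]]]:
    """Average-linkage clustering of traits on the distance 1 - |r|.

    Returns the dendrogram leaf order and flat trait groups cut at ``height``
    (distance scale: 0 = perfectly correlated, 1 = uncorrelated).
    """
    r = cm.r.copy()
    if r.isna().any().any():
        warnings.warn("correlation matrix has missing entries; "
                      "using pairwise-complete fallback (NaN -> 0)")
        r = r.fillna(0.0)
    traits = list(r.index)
    d = 1.0 - r.abs().to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    order = [traits[i] for i in hierarchy.leaves_list(link)]
    labels = hierarchy.fcluster(link, t=height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for t, lab in zip(traits, labels):
        groups.setdefault(lab, []).append(t)
    # report groups in leaf order
    ordered = sorted(groups.values(), key=lambda g: min(order.index(t) for t in g))
    return order, ordered
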