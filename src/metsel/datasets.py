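"""Bundled reference tables from a published multi-environment maize trial.

A Stage-III evaluation of 75 tropical pre-released maize hybrids (12 agronomic
traits, seven environments across optimal, managed-drought and managed-
waterlogging regimes in India, winter 2017 / summer-rainy 2018) published its
per-regime MGIDI values, factor-analysis summaries, genetic parameters and
selection-gain tables.  Those printed tables are shipped here as plain CSVs:
they are the inputs for deterministic recomputation checks (selection counts,
cross-regime overlap, factor-variance arithmetic, selection-differential
arithmetic) since the underlying plot data were not deposited.

Note: in the gains table, the drought TW row is shipped verbatim although its
printed Xo/Xs are inconsistent with the printed SD sign; in the genetic
parameter table the optimal GY CV ratio was garbled in print and is stored
as cv_g / cv_r.
"""

from __future__ import annotations

import importlib.resources as resources

import pandas as pd

__all__ = [
    "load_reference_mgidi",
    "load_reference_factor_summary",
    "load_reference_selection_gains",
    "load_reference_genetic_parameters",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("metsel").joinpath("refdata", name).open() as fh:
        return pd.read_csv(fh)


def load_reference_mgidi() -> pd.DataFrame:
    """MGIDI values of the 75 hybrids per regime; index = hybrid number."""
    return _read("maize_mgidi_values.csv").set_index("hybrid")


def load_reference_factor_summary() -> pd.DataFrame:
    """Retained-factor eigenvalues, variance % and cumulative % per regime."""
    return _read("maize_factor_summary.csv")


def load_reference_selection_gains() -> pd.DataFrame:
    """Per-trait selection-differential rows (Xo, Xs, SD, SD%) per regime."""
    return _read("maize_selection_gains.csv")


def load_reference_genetic_parameters() -> pd.DataFrame:
    """LRT statistics and genetic parameters per trait and regime."""
    return _read("maize_genetic_parameters.csv")
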