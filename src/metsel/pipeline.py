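"""Per-regime analysis pipeline: fit -> parameters -> BLUPs -> correlations ->
MGIDI -> gains -> cross-regime overlap, with table rendering.

The pipeline mirrors the per-regime workflow of a multi-environment hybrid
selection study: each soil-moisture regime is analyzed independently (its own
mixed models, genetic parameters, factor analysis and selection), and a final
overlap section reports which hybrids were selected under every regime.  The
analysis path contains no randomness: rerunning on the same data and config
produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mgidi as mg
from .correlation import genetic_correlations
from .data import METDataset, MetDataError, TraitSpec, subset_regime
from .mixed import (blup_table, fit_trait_model, genetic_parameters,
                    lrt_random_term)

__all__ = ["PipelineConfig", "RegimeSection", "RunReport", "run_pipeline",
           "render_report"]

log = logging.getLogger("metsel.pipeline")

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run from data + config alone."""

    traits: list[TraitSpec]
    regimes: list[str] | None = None      # None = every regime in the data
    intensity: float = 0.15
    n_factors: int | None = None          # override of the Kaiser rule
    compute_lrt: bool = True
    lrt_boundary: bool = False            # boundary chi-square mixture p-values
    use_raw_means: bool = False           # raw genotype means instead of BLUPs
    reml_tol: float = 1e-8
    reml_max_iter: int = 500

    def __post_init__(self) -> None:
        if not self.traits:
            raise MetDataError("config must name at least one trait")
        if not (0.0 < self.intensity < 1.0):
            raise MetDataError("intensity must be in (0,1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traits"] = [dataclasses.asdict(t) for t in self.traits]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["traits"] = [TraitSpec(**t) for t in d["traits"]]
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RegimeSection:
    regime: str
    params_table: pd.DataFrame        # variance components + genetic parameters
    blups: pd.DataFrame               # genotype x trait predicted means
    correlations: pd.DataFrame        # trait x trait genetic correlations
    factor_summary: pd.DataFrame      # eigenvalue / variance% / cumulative%
    loadings: pd.DataFrame            # rotated loadings, traits x factors
    index_table: pd.DataFrame         # MGIDI value, rank, selected flag
    omega: pd.DataFrame               # strengths/weaknesses shares
    gains_table: pd.DataFrame         # selection differentials per trait
    selected: list[str]


@dataclass
class RunReport:
    config: PipelineConfig
    config_hash: str
    version: str
    sections: dict[str, RegimeSection]
    overlap: dict | None


def _analyze_regime(ds: METDataset, cfg: PipelineConfig, regime: str) -> RegimeSection:
    t0 = time.perf_counter()
    sub = subset_regime(ds, regime)
    if sub.e < 2:
        raise MetDataError(f"regime {regime!r} has {sub.e} environment(s); need >= 2")
    fits, rows = {}, []
    for trait in sub.trait_names:
        fit = fit_trait_model(sub, trait, tol=cfg.reml_tol,
                              max_iter=cfg.reml_max_iter)
        if not fit.converged:
            log.warning("regime %s trait %s: EM-REML not converged", regime, trait)
        fits[trait] = fit
        gp = genetic_parameters(fit.vc, sub, trait, fit)
        row = {
            "trait": trait,
            "sigma2_g": fit.vc.sigma2_g, "sigma2_ge": fit.vc.sigma2_ge,
            "sigma2_block": fit.vc.sigma2_block, "sigma2_e": fit.vc.sigma2_e,
            "sigma2_p": fit.vc.sigma2_p,
            "h2mg": gp.h2mg, "accuracy": gp.accuracy, "r2ge": gp.r2ge,
            "cv_g": gp.cv_g, "cv_r": gp.cv_r, "cv_ratio": gp.cv_ratio,
            "env_f": gp.env_f, "grand_mean": gp.grand_mean,
            "converged": fit.converged,
        }
        if cfg.compute_lrt:
            for term, label in (("genotype", "g"), ("gei", "ge")):
                res = lrt_random_term(sub, trait, term, boundary=cfg.lrt_boundary,
                                      full=fit, tol=cfg.reml_tol,
                                      max_iter=cfg.reml_max_iter)
                row[f"lrt_{label}"] = res.statistic
                row[f"p_{label}"] = res.p_value
        rows.append(row)
    params = pd.DataFrame(rows).set_index("trait")

    blups = blup_table(fits, sub)
    cm = genetic_correlations(blups) if not cfg.use_raw_means else \
        genetic_correlations(ds=sub, use_raw_means=True)

    source = blups.values if not cfg.use_raw_means else \
        sub.table.groupby("genotype")[sub.trait_names].mean()
    rt = mg.rescale_traits(source, cfg.traits)
    fm = mg.fit_efa(rt, n_factors=cfg.n_factors)
    st = mg.factor_scores(rt, fm)
    result = mg.compute_mgidi(st)
    result = mg.select_genotypes(result, cfg.intensity)
    result = mg.strengths_weaknesses(st, result)
    gains = mg.selection_gains(source, result.selected, fm, cfg.traits)

    factor_summary = pd.DataFrame({
        "factor": np.arange(1, fm.n_factors + 1),
        "eigenvalue": fm.eigenvalues[:fm.n_factors],
        "variance_pct": fm.variance_pct[:fm.n_factors],
        "cumulative_pct": fm.cumulative_pct[:fm.n_factors],
    })
    index_table = pd.DataFrame({
        "MGIDI": result.mgidi,
        "rank": result.ranks,
        "selected": result.mgidi.index.isin(result.selected),
    }).sort_values("rank")
    gains_table = pd.DataFrame([dataclasses.asdict(r) for r in gains])
    gains_table = gains_table.rename(columns={
        "trait": "Trait", "factor": "Factor", "sense": "Sense",
        "goal_met": "Goal", "xo": "Xo", "xs": "Xs", "sd": "SD", "sd_pct": "SD%"})
    gains_table = gains_table[["Trait", "Factor", "Sense", "Goal",
                               "Xo", "Xs", "SD", "SD%"]]
    log.info("regime %s analyzed in %.2fs", regime, time.perf_counter() - t0)
    return RegimeSection(
        regime=regime, params_table=params, blups=blups.values,
        correlations=cm.r, factor_summary=factor_summary, loadings=fm.loadings,
        index_table=index_table, omega=result.omega, gains_table=gains_table,
        selected=result.selected,
    )


def run_pipeline(ds: METDataset, cfg: PipelineConfig) -> RunReport:
    """Run the full per-regime workflow and assemble the report."""
    regimes = cfg.regimes or sorted(set(ds.table["regime"]))
    sections = {}
    for regime in regimes:
        try:
            sections[regime] = _analyze_regime(ds, cfg, regime)
        except Exception as exc:
            raise MetDataError(f"pipeline failed in regime {regime!r}: {exc}") from exc
    overlap = None
    if len(sections) >= 2:
        overlap = mg.cross_regime_overlap(
            {r: s.selected for r, s in sections.items()})
    return RunReport(config=cfg, config_hash=cfg.config_hash, version=VERSION,
                     sections=sections, overlap=overlap)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_TABLES = ("params_table", "blups", "correlations", "factor_summary",
           "loadings", "index_table", "omega", "gains_table")


def _check_complete(rr: RunReport) -> None:
    for regime, sec in rr.sections.items():
        if not sec.selected:
            raise MetDataError(f"regime {regime!r} has an empty selection; "
                               "refusing to render")


def render_report(rr: RunReport, fmt: str, outdir: str | os.PathLike) -> list[str]:
    """Write the report tables as 'csv-bundle', 'json' or 'markdown'.

    Numbers are identical across formats (full precision); markdown mirrors
    the study-table layouts for visual diffing.  Returns the files written.
    """
    if fmt not in ("csv-bundle", "json", "markdown"):
        raise MetDataError(f"unknown report format {fmt!r}")
    _check_complete(rr)
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    if fmt == "csv-bundle":
        for regime, sec in rr.sections.items():
            for name in _TABLES:
                path = os.path.join(outdir, f"{regime}_{name}.csv")
                getattr(sec, name).to_csv(path)
                written.append(path)
        if rr.overlap is not None:
            path = os.path.join(outdir, "overlap.json")
            with open(path, "w") as fh:
                json.dump(rr.overlap, fh, indent=1, sort_keys=True)
            written.append(path)
        meta = os.path.join(outdir, "run.json")
        with open(meta, "w") as fh:
            json.dump({"version": rr.version, "config_hash": rr.config_hash,
                       "config": rr.config.to_dict()}, fh, indent=1, sort_keys=True)
        written.append(meta)
    elif fmt == "json":
        payload = {"version": rr.version, "config_hash": rr.config_hash,
                   "config": rr.config.to_dict(), "overlap": rr.overlap,
                   "sections": {}}
        for regime, sec in rr.sections.items():
            payload["sections"][regime] = {
                name: json.loads(getattr(sec, name).to_json(orient="split"))
                for name in _TABLES}
            payload["sections"][regime]["selected"] = sec.selected
        path = os.path.join(outdir, "report.json")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        written.append(path)
    else:  # markdown
        lines = [f"# Multi-environment selection report",
                 f"",
                 f"version {rr.version}, config {rr.config_hash}", ""]
        for regime, sec in rr.sections.items():
            lines += [f"## Regime: {regime}", ""]
            lines += ["### Genetic parameters", "",
                      sec.params_table.to_markdown(), ""]
            lines += ["### Factors", "", sec.factor_summary.to_markdown(index=False),
                      "", sec.loadings.to_markdown(), ""]
            lines += ["### MGIDI ranking", "", sec.index_table.to_markdown(), ""]
            lines += ["### Selection gains", "",
                      sec.gains_table.to_markdown(index=False), ""]
        if rr.overlap is not None:
            lines += ["## Cross-regime overlap", "",
                      "```json", json.dumps(rr.overlap, indent=1, sort_keys=True),
                      "```", ""]
        path = os.path.join(outdir, "report.md")
        with open(path, "w") as fh:
            fh.write("\n".join(lines))
        written.append(path)
    return written
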