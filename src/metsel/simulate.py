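"""Synthetic multi-environment maize trial generator.

Emulates the stated world of the analysis: 75 hybrids scored for 12 traits in
seven environments spread over three soil-moisture regimes (3 optimal, 2
managed drought, 2 managed waterlogging), laid out as an alpha-lattice with 2
complete replicates and incomplete blocks within replicate.  Plot values are

    y = trait mean + environment effect (fixed)
        + genotype effect + genotype-x-environment effect
        + incomplete-block effect + residual,

with genotype effects drawn from a zero-mean multivariate normal whose
correlation structure is induced by a low-rank factor loading matrix (a yield
factor, a phenology factor and an ear factor), so that the exploratory factor
analysis downstream has true structure to recover.  All randomness flows from
a single integer seed.

Default trait means and variance scales reproduce the magnitudes observed for
this germplasm under optimal moisture (means, phenotypic variances, GEI share
R2ge and genotype-mean heritability h2mg per trait); the variance components
sigma2_g, sigma2_ge, sigma2_e are solved from those three summaries, see
``components_from_summary``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import METDataset, TraitSpec, ConfigError

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "components_from_summary",
    "default_trait_specs",
    "default_config",
    "sample_genetic_effects",
    "simulate_met",
    "inject_missing",
    "spike_ideal_genotypes",
    "spike_to_ideal",
]

# Per-trait summaries of the optimal-regime world being emulated:
# (direction, grand mean, phenotypic variance sigma2_p, R2ge, CVg %, CVr %).
# Components derive as sigma2_g = (CVg * mean / 100)^2, sigma2_e likewise
# from CVr, sigma2_ge = R2ge * sigma2_p: all directly stated, always
# consistent (the printed h2mg rows are not exactly recoverable from the
# printed sigma2_p/R2ge trio for every trait, so h2mg is not used here).
_TRAIT_WORLD: dict[str, tuple[str, float, float, float, float, float]] = {
    "D50A": ("decrease", 67.18, 4.60, 0.12, 2.32, 1.72),
    "D50S": ("decrease", 69.60, 5.80, 0.16, 2.40, 1.77),
    "ASI":  ("decrease", 2.42, 1.09, 0.39, 5.79, 32.47),
    "PH":   ("increase", 170.96, 297.50, 0.59, 3.91, 4.87),
    "EH":   ("increase", 90.66, 169.0, 0.18, 8.68, 9.21),
    "SPAD": ("increase", 48.30, 33.57, 0.72, 2.86, 5.63),
    "EL":   ("increase", 18.26, 2.03, 0.62, 3.15, 3.56),
    "EG":   ("increase", 4.34, 0.12, 0.60, 3.33, 3.67),
    "KRE":  ("increase", 14.80, 1.39, 0.58, 4.00, 3.23),
    "KNR":  ("increase", 33.73, 12.67, 0.79, 2.95, 3.71),
    "TW":   ("increase", 29.05, 5.89, 0.70, 3.49, 2.92),
    "GY":   ("increase", 7.87, 2.08, 0.62, 9.76, 5.27),
}
_WORLD_E, _WORLD_B = 3, 2

# Genetic factor loadings inducing trait correlations: a vegetative/yield
# factor, a phenology factor, and an ear-architecture factor.
_DEFAULT_LOADINGS: dict[str, tuple[float, float, float]] = {
    "D50A": (0.00, 0.85, 0.00),
    "D50S": (0.00, 0.90, 0.00),
    "ASI":  (-0.10, 0.50, 0.00),
    "PH":   (0.75, 0.10, 0.00),
    "EH":   (0.70, 0.15, 0.00),
    "SPAD": (0.55, 0.00, 0.10),
    "EL":   (0.65, 0.00, 0.15),
    "EG":   (0.10, 0.00, 0.75),
    "KRE":  (0.00, 0.00, 0.80),
    "KNR":  (0.75, -0.10, 0.10),
    "TW":   (0.20, 0.45, 0.10),
    "GY":   (0.70, -0.15, 0.35),
}

_DEFAULT_ENVIRONMENTS = [
    ("E1", "optimal"),
    ("E2", "drought"),
    ("E3", "drought"),
    ("E4", "optimal"),
    ("E5", "waterlogging"),
    ("E6", "optimal"),
    ("E7", "waterlogging"),
]


def components_from_summary(sigma2_p: float, r2ge: float, h2mg: float,
                            e: int, b: int) -> tuple[float, float, float]:
    """Solve (sigma2_g, sigma2_ge, sigma2_e) from summary genetic parameters.

    Given the phenotypic variance sigma2_p = sigma2_g + sigma2_ge + sigma2_e,
    the GEI determination R2ge = sigma2_ge / sigma2_p and the genotype-mean
    heritability h2mg = sigma2_g / (sigma2_g + sigma2_ge/e + sigma2_e/(e*b)),
    the three components are identified exactly.
    """
    s_ge = r2ge * sigma2_p
    rest = sigma2_p - s_ge  # sigma2_g + sigma2_e
    denom = 1.0 - h2mg * (1.0 - 1.0 / (e * b))
    s_g = h2mg * (s_ge / e + rest / (e * b)) / denom
    s_e = rest - s_g
    if min(s_g, s_ge, s_e) < 0:
        raise ConfigError("summary parameters imply a negative variance component")
    return s_g, s_ge, s_e


def default_trait_specs() -> list[TraitSpec]:
    return [TraitSpec(name, spec[0]) for name, spec in _TRAIT_WORLD.items()]


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the emulated trial."""

    n_genotypes: int = 75
    environments: list[tuple[str, str]] = field(
        default_factory=lambda: list(_DEFAULT_ENVIRONMENTS))
    n_reps: int = 2
    blocks_per_rep: int = 5
    trait_specs: list[TraitSpec] = field(default_factory=default_trait_specs)
    trait_means: dict[str, float] = field(
        default_factory=lambda: {t: v[1] for t, v in _TRAIT_WORLD.items()})
    sigma2_g: dict[str, float] = field(default_factory=dict)
    sigma2_ge: dict[str, float] = field(default_factory=dict)
    sigma2_block: dict[str, float] = field(default_factory=dict)
    sigma2_e: dict[str, float] = field(default_factory=dict)
    genetic_loadings: pd.DataFrame | None = None
    env_effect_scale: float = 0.4  # fixed env spread, in phenotypic SDs
    seed: int = 0

    def __post_init__(self) -> None:
        names = [t.name for t in self.trait_specs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate trait names in config")
        # fill unspecified variance components from the emulated world
        for t in names:
            if t in _TRAIT_WORLD and t not in self.sigma2_g:
                _, mean, s2p, r2ge, cv_g, cv_r = _TRAIT_WORLD[t]
                self.sigma2_g.setdefault(t, (cv_g * mean / 100.0) ** 2)
                self.sigma2_ge.setdefault(t, r2ge * s2p)
                self.sigma2_e.setdefault(t, (cv_r * mean / 100.0) ** 2)
            # incomplete-block variance is small relative to residual
            self.sigma2_block.setdefault(t, 0.05 * self.sigma2_e.get(t, 1.0))
        missing = [t for t in names
                   if t not in self.sigma2_g or t not in self.sigma2_ge
                   or t not in self.sigma2_e]
        if missing:
            raise ConfigError(f"variance components not specified for traits: {missing}")
        for comp in (self.sigma2_g, self.sigma2_ge, self.sigma2_block, self.sigma2_e):
            for t in names:
                if comp.get(t, 0.0) < 0:
                    raise ConfigError(f"negative variance for trait {t!r}")
        if self.genetic_loadings is None:
            lam = pd.DataFrame(
                {t: _DEFAULT_LOADINGS.get(t, (0.0, 0.0, 0.0)) for t in names}
            ).T
            lam.columns = [f"F{j+1}" for j in range(lam.shape[1])]
            self.genetic_loadings = lam
        if list(self.genetic_loadings.index) != names:
            raise ConfigError("genetic_loadings rows must match the trait list")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.trait_specs]

    @property
    def genotype_ids(self) -> list[str]:
        return [f"G{i+1:03d}" for i in range(self.n_genotypes)]


@dataclass
class SimulatedTruth:
    """Ground truth behind one simulated dataset."""

    genotype_effects: pd.DataFrame            # genotype x trait
    gei_effects: pd.DataFrame                 # (genotype, environment) x trait
    block_effects: pd.DataFrame               # (environment, rep, block) x trait
    env_effects: pd.DataFrame                 # environment x trait (fixed)
    variance_components: dict[str, dict[str, float]]
    genetic_correlation: pd.DataFrame         # target trait x trait correlation
    spiked: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "variance_components": self.variance_components,
            "spiked": self.spiked,
            "genotype_effects": self.genotype_effects.round(10).to_dict(),
            "env_effects": self.env_effects.round(10).to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _target_correlation(cfg: SimulationConfig) -> pd.DataFrame:
    lam = cfg.genetic_loadings.to_numpy(float)
    comm = (lam ** 2).sum(axis=1)
    if (comm > 1.0 + 1e-12).any():
        raise ConfigError("genetic loading rows must have squared norm <= 1")
    corr = lam @ lam.T + np.diag(1.0 - comm)  # uniquenesses make diagonal 1
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-8:
        raise ConfigError("genetic loading matrix implies a non-PSD correlation")
    return pd.DataFrame(corr, index=cfg.trait_names, columns=cfg.trait_names)


def sample_genetic_effects(cfg: SimulationConfig,
                           rng: np.random.Generator | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw correlated genotype effects; returns (effects, target correlation).

    Effects are multivariate normal with covariance D^1/2 C D^1/2, where C is
    the factor-induced correlation and D holds the per-trait sigma2_g.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    corr = _target_correlation(cfg)
    sd = np.sqrt([cfg.sigma2_g[t] for t in cfg.trait_names])
    cov = corr.to_numpy() * np.outer(sd, sd)
    draws = rng.multivariate_normal(np.zeros(len(sd)), cov, size=cfg.n_genotypes,
                                    method="svd")
    eff = pd.DataFrame(draws, index=cfg.genotype_ids, columns=cfg.trait_names)
    return eff, corr


def simulate_met(cfg: SimulationConfig) -> tuple[METDataset, SimulatedTruth]:
    """Simulate one complete multi-environment trial per the config."""
    rng = np.random.default_rng(cfg.seed)
    traits = cfg.trait_names
    geno = cfg.genotype_ids
    g_eff, corr = sample_genetic_effects(cfg, rng)

    envs = [e for e, _ in cfg.environments]
    regime_of = dict(cfg.environments)
    sd_p = {t: np.sqrt(cfg.sigma2_g[t] + cfg.sigma2_ge[t] + cfg.sigma2_e[t])
            for t in traits}
    # fixed environment main effects: an even spread scaled per trait
    spread = np.linspace(-1.0, 1.0, len(envs)) if len(envs) > 1 else np.zeros(1)
    env_eff = pd.DataFrame(
        {t: spread * cfg.env_effect_scale * sd_p[t] for t in traits}, index=envs)

    gei_index = pd.MultiIndex.from_product([geno, envs], names=["genotype", "environment"])
    gei = pd.DataFrame(
        {t: rng.normal(0.0, np.sqrt(cfg.sigma2_ge[t]), len(gei_index)) for t in traits},
        index=gei_index)

    rows = []
    block_rows = {}
    for env in envs:
        for rep in range(1, cfg.n_reps + 1):
            order = rng.permutation(cfg.n_genotypes)
            chunks = np.array_split(order, cfg.blocks_per_rep)  # one block may be smaller
            for bi, chunk in enumerate(chunks, start=1):
                block_id = f"{env}_R{rep}_B{bi}"
                block_rows[(env, rep, block_id)] = {
                    t: rng.normal(0.0, np.sqrt(cfg.sigma2_block[t])) for t in traits}
                for gi in chunk:
                    rows.append((geno[gi], env, regime_of[env], rep, block_id))
    plots = pd.DataFrame(rows, columns=["genotype", "environment", "regime",
                                        "replicate", "block"])
    block_eff = pd.DataFrame(block_rows).T
    block_eff.index.names = ["environment", "replicate", "block"]

    n = len(plots)
    for t in traits:
        vals = (
            cfg.trait_means[t]
            + env_eff.loc[plots["environment"], t].to_numpy()
            + g_eff.loc[plots["genotype"], t].to_numpy()
            + gei.loc[pd.MultiIndex.from_frame(plots[["genotype", "environment"]]), t].to_numpy()
            + block_eff.loc[pd.MultiIndex.from_frame(
                plots[["environment", "replicate", "block"]]), t].to_numpy()
            + rng.normal(0.0, np.sqrt(cfg.sigma2_e[t]), n)
        )
        plots[t] = vals

    ds = METDataset(plots, list(cfg.trait_specs))
    truth = SimulatedTruth(
        genotype_effects=g_eff,
        gei_effects=gei,
        block_effects=block_eff,
        env_effects=env_eff,
        variance_components={
            t: {"sigma2_g": cfg.sigma2_g[t], "sigma2_ge": cfg.sigma2_ge[t],
                "sigma2_block": cfg.sigma2_block[t], "sigma2_e": cfg.sigma2_e[t]}
            for t in traits},
        genetic_correlation=corr,
    )
    return ds, truth


def inject_missing(ds: METDataset, rate: float, seed: int = 0) -> METDataset:
    """Set a Bernoulli(rate) subset of plot values to missing."""
    if not (0.0 <= rate < 1.0):
        raise ConfigError(f"missing rate must be in [0,1), got {rate}")
    rng = np.random.default_rng(seed)
    df = ds.table.copy()
    for t in ds.trait_names:
        mask = rng.random(len(df)) < rate
        df.loc[mask, t] = np.nan
    return METDataset(df, list(ds.traits))


def spike_to_ideal(ds: METDataset, truth: SimulatedTruth, cfg: SimulationConfig,
                   ids: list[str], sd: float = 2.0) -> METDataset:
    """Place named genotypes exactly ``sd`` genetic SD toward the ideotype.

    Unlike :func:`spike_ideal_genotypes`, which adds a fixed shift on top of
    whatever genetic effect a genotype happened to draw, this neutralizes the
    genotype's own draw (known from the simulation truth) so its genetic value
    lands at +sd*sigma_g for every increase-trait and -sd*sigma_g for every
    decrease-trait: a controlled near-ideal genotype for selection-power
    studies.  Records the ids in ``truth.spiked``.
    """
    direction = {t.name: t.direction for t in ds.traits}
    out = ds
    for g in ids:
        shift = {}
        for t in ds.trait_names:
            target = sd * np.sqrt(cfg.sigma2_g[t])
            draw = float(truth.genotype_effects.loc[g, t])
            shift[t] = target - draw if direction[t] == "increase" else target + draw
        out = spike_ideal_genotypes(out, [g], shift)
    truth.spiked = sorted(set(truth.spiked) | set(ids))
    return out


def spike_ideal_genotypes(ds: METDataset, ids: list[str],
                          shift: dict[str, float]) -> METDataset:
    """Shift named genotypes toward the ideotype.

    Each listed trait is moved by ``shift`` in its desirable direction
    (added for increase-traits, subtracted for decrease-traits), in every plot
    of the named genotypes.  Unlisted traits are untouched.
    """
    unknown = set(ids) - set(ds.table["genotype"])
    if unknown:
        raise ConfigError(f"unknown genotype id(s): {sorted(unknown)}")
    df = ds.table.copy()
    mask = df["genotype"].isin(ids)
    for t, delta in shift.items():
        spec = ds.trait_spec(t)
        signed = delta if spec.direction == "increase" else -delta
        df.loc[mask, t] = df.loc[mask, t] + signed
    return METDataset(df, list(ds.traits))
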