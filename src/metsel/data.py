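"""Plot-level multi-environment-trial (MET) data model and field formulas.

A MET dataset holds plot means for a set of maize hybrids evaluated in several
environments (location x season combinations), each environment belonging to
exactly one soil-moisture regime (optimal, managed drought, managed
waterlogging).  The trial layout is a resolvable incomplete-block (alpha
lattice) design: complete replicates within environment, incomplete blocks
within replicate.

Also implemented here are the two field formulas used when preparing such
trials: cumulative growing degree days (used to schedule drought stress
imposition) and standardization of plot fresh ear weight to grain yield in
t/ha at a fixed moisture content.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIMES",
    "KEY_COLUMNS",
    "TraitSpec",
    "WeatherRecord",
    "HarvestRecord",
    "METDataset",
    "MetDataError",
    "StructuralError",
    "ConfigError",
    "read_met_table",
    "write_met_table",
    "subset_regime",
    "cumulative_gdd",
    "standardize_grain_yield",
    "STRESS_WITHDRAWAL_GDD",
    "RESCUE_IRRIGATION_GDD",
]

#: Soil-moisture regimes a trial environment can be managed under.
REGIMES = ("optimal", "drought", "waterlogging")

#: Mandatory identifier columns of a long-format phenotype table.
KEY_COLUMNS = ["genotype", "environment", "regime", "replicate", "block"]

#: Cumulative GDD (base 10 C, from life irrigation) at which irrigation is
#: withdrawn to impose reproductive-stage drought stress.
STRESS_WITHDRAWAL_GDD = 550.0
#: Cumulative GDD at which rescue irrigation releases the drought stress.
RESCUE_IRRIGATION_GDD = 1000.0


class MetDataError(ValueError):
    """Base error for invalid MET data."""


class StructuralError(MetDataError):
    """The table violates a structural invariant (keys, regime map)."""


class ConfigError(MetDataError):
    """The trait configuration does not match the data."""


@dataclass(frozen=True)
class TraitSpec:
    """An analyzed trait and the direction in which gains are desirable.

    direction 'increase' means larger values are better (e.g. grain yield,
    plant height); 'decrease' means smaller values are better (e.g. days to
    anthesis, anthesis-silking interval).
    """

    name: str
    direction: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ConfigError(
                f"trait {self.name!r}: direction must be 'increase' or "
                f"'decrease', got {self.direction!r}"
            )


@dataclass(frozen=True)
class WeatherRecord:
    """Daily temperature extremes (degrees C)."""

    date: object
    tmax: float
    tmin: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise MetDataError(
                f"weather on {self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )


@dataclass(frozen=True)
class HarvestRecord:
    """Per-plot harvest measurements feeding grain-yield standardization.

    fresh_ear_weight in kg/plot, moisture (MC) in percent, shelling (SH) as a
    fraction in [0, 1], plot_area in m^2, adjusted_moisture the standardized
    moisture percentage grain yield is expressed at (12.5% by convention).
    """

    fresh_ear_weight: float
    moisture: float
    shelling: float
    plot_area: float
    adjusted_moisture: float = 12.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.moisture < 100.0):
            raise MetDataError(f"moisture must be in [0, 100), got {self.moisture}")
        if not (0.0 <= self.shelling <= 1.0):
            raise MetDataError(f"shelling must be a fraction in [0,1], got {self.shelling}")
        if self.plot_area <= 0:
            raise MetDataError(f"plot_area must be > 0, got {self.plot_area}")
        if not (0.0 <= self.adjusted_moisture < 100.0):
            raise MetDataError(
                f"adjusted_moisture must be in [0, 100), got {self.adjusted_moisture}"
            )


@dataclass
class METDataset:
    """Long-format plot-level phenotypes plus design metadata.

    ``table`` has the key columns genotype, environment, regime, replicate,
    block, followed by one float column per trait (NaN = missing plot value).
    """

    table: pd.DataFrame
    traits: list[TraitSpec]

    def __post_init__(self) -> None:
        self.validate()

    # -- design metadata -------------------------------------------------
    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.table["environment"].unique())

    @property
    def e(self) -> int:
        """Number of environments."""
        return self.table["environment"].nunique()

    @property
    def b(self) -> int:
        """Number of complete replicates per environment (the b of h2mg)."""
        return int(self.table.groupby("environment")["replicate"].nunique().max())

    @property
    def regime_map(self) -> dict[str, str]:
        return (
            self.table.drop_duplicates("environment")
            .set_index("environment")["regime"]
            .to_dict()
        )

    def trait_spec(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise ConfigError(f"unknown trait {name!r}")

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.table
        missing_cols = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing_cols:
            raise StructuralError(f"missing key columns: {missing_cols}")
        names = self.trait_names
        if len(set(names)) != len(names):
            raise ConfigError("trait names must be unique")
        absent = [n for n in names if n not in df.columns]
        if absent:
            raise ConfigError(f"trait columns absent from table: {absent}")
        bad_regime = set(df["regime"]) - set(REGIMES)
        if bad_regime:
            raise StructuralError(f"unknown regimes: {sorted(bad_regime)}")
        multi = df.groupby("environment")["regime"].nunique()
        if (multi > 1).any():
            offenders = multi[multi > 1].index.tolist()
            raise StructuralError(
                f"environment(s) mapped to more than one regime: {offenders}"
            )
        if (df["replicate"].astype(int) < 1).any():
            raise StructuralError("replicate indices must be >= 1")
        dup = df.duplicated(subset=["genotype", "environment", "replicate"])
        if dup.any():
            rows = df.loc[dup, ["genotype", "environment", "replicate"]]
            raise StructuralError(
                f"duplicate (genotype, environment, replicate) rows:\n{rows.head()}"
            )

    def __len__(self) -> int:
        return len(self.table)

    def equals(self, other: "METDataset") -> bool:
        return self.traits == other.traits and self.table.equals(other.table)


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_met_table(path: str | os.PathLike, trait_config: Sequence[TraitSpec]) -> METDataset:
    """Read a long-format CSV/TSV phenotype table into a validated dataset.

    Expected header: genotype, environment, regime, replicate, block, then one
    column per configured trait.  Empty cells become missing plot values.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip",
                     dtype={c: str for c in
                            ("genotype", "environment", "regime", "block")})
    return _from_frame(df, trait_config)


def _from_frame(df: pd.DataFrame, trait_config: Sequence[TraitSpec]) -> METDataset:
    names = [t.name for t in trait_config]
    absent = [n for n in names if n not in df.columns]
    if absent:
        raise ConfigError(f"configured trait column(s) missing from file: {absent}")
    df = df[KEY_COLUMNS + names].copy()
    df["replicate"] = df["replicate"].astype(int)
    for n in names:
        df[n] = pd.to_numeric(df[n], errors="coerce").astype(float)
    return METDataset(df.reset_index(drop=True), list(trait_config))


def write_met_table(ds: METDataset, path: str | os.PathLike) -> None:
    """Write a dataset back to CSV/TSV; read_met_table round-trips it exactly.

    Floats are written with 17 significant digits so write->read is
    bit-identical.
    """
    ds.table.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def subset_regime(ds: METDataset, regime: str) -> METDataset:
    """Restrict a dataset to the environments of one soil-moisture regime.

    The per-regime mixed-model analysis always starts here: each regime is
    fitted separately, with its own environment count e.
    """
    if regime not in REGIMES:
        raise MetDataError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    sub = ds.table[ds.table["regime"] == regime]
    if sub.empty:
        raise MetDataError(f"no environments under regime {regime!r}")
    return METDataset(sub.reset_index(drop=True), list(ds.traits))


def cumulative_gdd(weather: Iterable[WeatherRecord], tbase: float = 10.0) -> np.ndarray:
    """Running cumulative growing degree days over a chronological series.

    Daily GDD = max((tmax + tmin)/2 - tbase, 0); days with mean temperature
    below the base contribute zero rather than a negative increment, so the
    cumulative series is non-negative and non-decreasing.
    """
    daily = []
    for rec in weather:
        if rec.tmax < rec.tmin:
            raise MetDataError(f"tmax < tmin on {rec.date}")
        daily.append(max((rec.tmax + rec.tmin) / 2.0 - tbase, 0.0))
    return np.cumsum(np.asarray(daily, dtype=float))


def standardize_grain_yield(h: HarvestRecord) -> float:
    """Convert plot fresh ear weight to grain yield (t/ha) at adjusted moisture.

    GY = FW * 10 * (100 - MC) * SH / ((100 - adjMC) * plot_area),
    with FW in kg/plot, plot_area in m^2 and SH a shelling fraction.
    """
    return (
        h.fresh_ear_weight
        * 10.0
        * (100.0 - h.moisture)
        * h.shelling
        / ((100.0 - h.adjusted_moisture) * h.plot_area)
    )
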