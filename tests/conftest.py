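import numpy as np
import pandas as pd
import pytest

from metsel import METDataset, SimulationConfig, TraitSpec, simulate_met


def small_sim_config(seed: int = 42, **overrides) -> SimulationConfig:
    """A fast two-regime world: 20 genotypes x 3 traits x 4 environments."""
    traits = [TraitSpec("GY", "increase"), TraitSpec("PH", "increase"),
              TraitSpec("ASI", "decrease")]
    base = dict(
        n_genotypes=20,
        environments=[("E1", "optimal"), ("E2", "optimal"),
                      ("E3", "drought"), ("E4", "drought")],
        n_reps=2,
        blocks_per_rep=4,
        trait_specs=traits,
        trait_means={"GY": 8.0, "PH": 170.0, "ASI": 2.5},
        sigma2_g={"GY": 1.0, "PH": 60.0, "ASI": 0.3},
        sigma2_ge={"GY": 0.5, "PH": 30.0, "ASI": 0.2},
        sigma2_block={"GY": 0.1, "PH": 5.0, "ASI": 0.05},
        sigma2_e={"GY": 1.0, "PH": 50.0, "ASI": 0.4},
        genetic_loadings=pd.DataFrame(
            {"F1": [0.8, 0.7, -0.3]}, index=["GY", "PH", "ASI"]),
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    cfg = small_sim_config()
    ds, truth = simulate_met(cfg)
    return cfg, ds, truth


@pytest.fixture()
def small_ds(small_world) -> METDataset:
    return small_world[1]


def rcbd_config(seed: int = 7, g: int = 15, e: int = 2, r: int = 2,
                s2g: float = 1.0, s2ge: float = 0.5, s2e: float = 1.0,
                regime: str = "optimal") -> SimulationConfig:
    """Balanced RCBD (one block per replicate, so no incomplete-block term)."""
    traits = [TraitSpec("Y", "increase")]
    return SimulationConfig(
        n_genotypes=g,
        environments=[(f"E{i+1}", regime) for i in range(e)],
        n_reps=r,
        blocks_per_rep=1,
        trait_specs=traits,
        trait_means={"Y": 10.0},
        sigma2_g={"Y": s2g},
        sigma2_ge={"Y": s2ge},
        sigma2_block={"Y": 0.0},
        sigma2_e={"Y": s2e},
        genetic_loadings=pd.DataFrame({"F1": [1.0]}, index=["Y"]),
        seed=seed,
    )


def anova_rcbd_components(ds: METDataset, trait: str):
    """Method-of-moments ANOVA estimators for a balanced RCBD across
    environments, with replicate-within-environment effects.

    sigma2_e = MS_resid; sigma2_ge = (MS_GE - MS_resid)/r;
    sigma2_g = (MS_G - MS_GE)/(r*e).  On balanced data with interior
    estimates these coincide with REML.
    """
    df = ds.table
    g = df["genotype"].nunique()
    e = df["environment"].nunique()
    r = df["replicate"].nunique()
    grand = df[trait].mean()
    gm = df.groupby("genotype")[trait].mean()
    em = df.groupby("environment")[trait].mean()
    gem = df.groupby(["genotype", "environment"])[trait].mean()
    rem = df.groupby(["environment", "replicate"])[trait].mean()

    ss_g = r * e * ((gm - grand) ** 2).sum()
    dev_ge = gem.copy()
    for (gi, ei), v in gem.items():
        dev_ge.loc[(gi, ei)] = v - gm[gi] - em[ei] + grand
    ss_ge = r * (dev_ge ** 2).sum()
    resid = df.apply(
        lambda row: row[trait]
        - gem[(row["genotype"], row["environment"])]
        - rem[(row["environment"], row["replicate"])]
        + em[row["environment"]],
        axis=1)
    ss_resid = (resid ** 2).sum()

    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    ms_resid = ss_resid / (e * (g - 1) * (r - 1))
    s2e = ms_resid
    s2ge = (ms_ge - ms_resid) / r
    s2g = (ms_g - ms_ge) / (r * e)
    return s2g, s2ge, s2e
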