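"""Multi-trait genotype-ideotype distance index (MGIDI).

The chain, run on a two-way table of predicted genotype means (genotypes x
traits) within one soil-moisture regime:

1. rescale every trait linearly to [0, 100] so that 100 is the desirable
   extreme (max for increase-traits, min for decrease-traits); rescaling is
   affine per trait, so the absolute inter-trait correlation structure is
   preserved;
2. exploratory factor analysis on the correlation matrix R of the rescaled
   table: principal-component extraction, Kaiser retention (eigenvalues > 1),
   varimax rotation with Kaiser normalization;
3. regression factor scores F = Z R^-1 A for the genotypes and for the
   ideotype, the hypothetical genotype with rescaled value 100 in every
   trait;
4. MGIDI_i = Euclidean distance between genotype i and the ideotype in
   factor-score space; the lowest-index genotypes are selected;
5. strengths/weaknesses: omega_ij, the share of genotype i's squared distance
   contributed by factor j (small omega = the factor's traits are close to
   the ideotype);
6. selection differentials per trait: the change of the selected-set mean
   relative to the population mean, in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MetDataError, TraitSpec
from .mixed import BlupTable

__all__ = [
    "RescaledTable",
    "FactorModel",
    "ScoreTable",
    "MgidiResult",
    "SelectionGainRow",
    "rescale_traits",
    "eigen_variance_table",
    "fit_efa",
    "varimax_rotate",
    "varimax_criterion",
    "factor_scores",
    "compute_mgidi",
    "select_genotypes",
    "strengths_weaknesses",
    "selection_gains",
    "cross_regime_overlap",
    "selection_differential_pct",
]


@dataclass
class RescaledTable:
    values: pd.DataFrame                 # g x p, entries in [0, 100]
    original_max: pd.Series              # eta_0 per trait
    original_min: pd.Series              # phi_0 per trait
    new_max: pd.Series                   # eta_n per trait (100 or 0)
    new_min: pd.Series                   # phi_n per trait
    directions: dict[str, str]


@dataclass
class FactorModel:
    correlation: pd.DataFrame            # R, p x p
    eigenvalues: np.ndarray              # all p, descending
    variance_pct: np.ndarray             # 100 * lambda / p
    cumulative_pct: np.ndarray
    n_factors: int
    initial_loadings: pd.DataFrame       # p x f, eigenvector * sqrt(lambda)
    loadings: pd.DataFrame               # p x f, varimax-rotated
    rotation: np.ndarray                 # f x f orthogonal
    communalities: pd.Series


@dataclass
class ScoreTable:
    z: pd.DataFrame                      # g x p standardized rescaled values
    scores: pd.DataFrame                 # g x f genotype factor scores
    ideotype_scores: pd.Series           # length f


@dataclass
class MgidiResult:
    mgidi: pd.Series                     # per genotype, >= 0
    ranks: pd.Series                     # 1..g, ascending MGIDI
    selected: list[str]
    intensity: float
    n_selected: int
    distances: pd.DataFrame | None = None    # g x f D_ij
    omega: pd.DataFrame | None = None        # g x f, rows sum to 1


@dataclass
class SelectionGainRow:
    trait: str
    factor: int
    sense: str
    xo: float
    xs: float
    sd: float
    sd_pct: float
    goal_met: bool


# ---------------------------------------------------------------------------

def rescale_traits(blups: BlupTable | pd.DataFrame,
                   specs: list[TraitSpec]) -> RescaledTable:
    """Linearly rescale each trait to [0, 100] with 100 at the desired extreme.

    rX_ij = (eta_n - phi_n) / (eta_0 - phi_0) * (theta_ij - eta_0) + eta_n,
    where eta_0/phi_0 are the observed max/min and eta_n/phi_n are 100/0 for
    increase-traits and 0/100 for decrease-traits.
    """
    X = blups.values if isinstance(blups, BlupTable) else blups
    by_name = {s.name: s for s in specs}
    missing = [c for c in X.columns if c not in by_name]
    if missing:
        raise MetDataError(f"no direction configured for trait(s): {missing}")
    out = {}
    eta0, phi0, etan, phin = {}, {}, {}, {}
    for t in X.columns:
        col = X[t].astype(float)
        hi, lo = float(col.max()), float(col.min())
        if hi == lo:
            raise MetDataError(f"trait {t!r} is constant; cannot rescale")
        if by_name[t].direction == "increase":
            new_max, new_min = 100.0, 0.0
        else:
            new_max, new_min = 0.0, 100.0
        out[t] = (new_max - new_min) / (hi - lo) * (col - hi) + new_max
        eta0[t], phi0[t], etan[t], phin[t] = hi, lo, new_max, new_min
    return RescaledTable(
        values=pd.DataFrame(out, index=X.index),
        original_max=pd.Series(eta0), original_min=pd.Series(phi0),
        new_max=pd.Series(etan), new_min=pd.Series(phin),
        directions={t: by_name[t].direction for t in X.columns},
    )


def eigen_variance_table(eigenvalues, p: int | None = None) -> pd.DataFrame:
    """Explained-variance percentages for a set of eigenvalues.

    variance% = 100 * lambda / p (p defaults to the total trait count, i.e.
    the number of eigenvalues supplied), with the running cumulative %.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if p is None:
        p = len(lam)
    pct = 100.0 * lam / p
    return pd.DataFrame({"eigenvalue": lam, "variance_pct": pct,
                         "cumulative_pct": np.cumsum(pct)})


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of the variance of squared loadings."""
    L2 = np.asarray(L) ** 2
    p = L2.shape[0]
    return float((L2 ** 2).sum() / p - ((L2.sum(axis=0) / p) ** 2).sum())


def varimax_rotate(loadings: pd.DataFrame | np.ndarray, *, kaiser: bool = True,
                   tol: float = 1e-10, max_iter: int = 1000
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by SVD gradient projection; returns (rotated, T).

    ``T`` is orthogonal with rotated = loadings @ T.  With ``kaiser=True``
    rows are normalized to unit communality during rotation (Kaiser
    normalization), the convention of standard statistical software.  A
    single factor is returned unchanged.
    """
    A = np.asarray(loadings, dtype=float)
    p, f = A.shape
    if f == 1:
        return A.copy(), np.eye(1)
    comm = np.sqrt((A ** 2).sum(axis=1))
    comm[comm == 0] = 1.0
    L = A / comm[:, None] if kaiser else A.copy()
    T = np.eye(f)
    d = 0.0
    for _ in range(max_iter):
        LT = L @ T
        grad = L.T @ (LT ** 3 - LT @ np.diag((LT ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        T = u @ vt
        d_new = s.sum()
        if d_new - d < tol * max(d, 1.0):
            break
        d = d_new
    rotated = (L @ T) * (comm[:, None] if kaiser else 1.0)
    return rotated, T


def fit_efa(rt: RescaledTable, n_factors: int | None = None) -> FactorModel:
    """Exploratory factor analysis of the rescaled table.

    Principal-component extraction from the correlation matrix R of the
    rescaled values: initial loadings are eigenvector_j * sqrt(lambda_j) for
    the f retained factors (Kaiser rule: lambda > 1, overridable via
    ``n_factors``), followed by varimax rotation.  Each rotated column is
    sign-flipped so its largest-magnitude loading is negative; the index
    downstream is provably invariant to this cosmetic convention.
    """
    X = rt.values
    g, p = X.shape
    R = X.corr()
    eigval, eigvec = np.linalg.eigh(R.to_numpy())
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    variance_pct = 100.0 * eigval / p
    f = int((eigval > 1.0).sum()) if n_factors is None else int(n_factors)
    if f < 1:
        raise MetDataError(
            "no eigenvalue exceeds 1 (Kaiser rule retains zero factors); "
            "pass n_factors to override")
    init = eigvec[:, :f] * np.sqrt(eigval[:f])
    rotated, T = varimax_rotate(init)
    # sign convention: largest-|loading| entry of each column negative
    for j in range(f):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] > 0:
            rotated[:, j] *= -1.0
            T[:, j] *= -1.0
    cols = [f"FA{j+1}" for j in range(f)]
    comm = pd.Series((rotated ** 2).sum(axis=1), index=X.columns)
    return FactorModel(
        correlation=R,
        eigenvalues=eigval,
        variance_pct=variance_pct,
        cumulative_pct=np.cumsum(variance_pct),
        n_factors=f,
        initial_loadings=pd.DataFrame(init, index=X.columns, columns=cols),
        loadings=pd.DataFrame(rotated, index=X.columns, columns=cols),
        rotation=T,
        communalities=comm,
    )


def _safe_r_inverse(R: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    try:
        return np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; applying ridge R + eps I")
        return np.linalg.inv(R + ridge * np.eye(R.shape[0]))


def factor_scores(rt: RescaledTable, fm: FactorModel) -> ScoreTable:
    """Regression factor scores F = Z R^-1 A for genotypes and the ideotype.

    Z standardizes each rescaled column to mean 0, sd 1 (sample sd, n-1).
    The ideotype is the row of 100s pushed through the same standardization
    and scoring map.
    """
    X = rt.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise MetDataError("constant rescaled column; cannot standardize")
    Z = (X - mu) / sd
    Rinv = _safe_r_inverse(fm.correlation.to_numpy())
    B = Rinv @ fm.loadings.to_numpy()          # p x f scoring coefficients
    F = Z.to_numpy() @ B
    z_id = ((100.0 - mu) / sd).to_numpy()
    id_scores = z_id @ B
    cols = list(fm.loadings.columns)
    return ScoreTable(
        z=Z,
        scores=pd.DataFrame(F, index=X.index, columns=cols),
        ideotype_scores=pd.Series(id_scores, index=cols),
    )


def compute_mgidi(st: ScoreTable) -> MgidiResult:
    """Euclidean genotype-ideotype distance in factor-score space, with ranks."""
    diff = st.scores - st.ideotype_scores
    mgidi = pd.Series(np.sqrt((diff ** 2).sum(axis=1)), index=st.scores.index,
                      name="MGIDI")
    ranks = mgidi.rank(method="first").astype(int)
    return MgidiResult(mgidi=mgidi, ranks=ranks, selected=[], intensity=np.nan,
                       n_selected=0)


def select_genotypes(mr: MgidiResult, intensity: float = 0.15) -> MgidiResult:
    """Select the round(g * intensity) genotypes closest to the ideotype.

    The count uses round-half-to-even; exact MGIDI ties at the cut are broken
    by input order with a warning.  Returns an updated result with the
    selected set filled in.
    """
    if not (0.0 < intensity < 1.0):
        raise MetDataError(f"intensity must be in (0,1), got {intensity}")
    g = len(mr.mgidi)
    n = int(round(g * intensity))
    if n == 0:
        raise MetDataError(f"intensity {intensity} selects zero of {g} genotypes")
    order = mr.ranks.sort_values(kind="stable")
    chosen = list(order.index[:n])
    cut_value = mr.mgidi[chosen[-1]]
    ties = (mr.mgidi == cut_value).sum()
    if ties > 1:
        warnings.warn(f"MGIDI tie at the selection cut (value {cut_value}); "
                      "broken by input order")
    return MgidiResult(mgidi=mr.mgidi, ranks=mr.ranks, selected=chosen,
                       intensity=intensity, n_selected=n,
                       distances=mr.distances, omega=mr.omega)


def strengths_weaknesses(st: ScoreTable, mr: MgidiResult) -> MgidiResult:
    """Per-factor contribution omega_ij = D_ij^2 / sum_j D_ij^2.

    D_ij is the absolute gap between genotype i and the ideotype on factor j.
    Rows sum to one; a genotype exactly at the ideotype has omega undefined
    and is reported as uniform 1/f with a warning.
    """
    D = (st.scores - st.ideotype_scores).abs()
    D2 = D ** 2
    tot = D2.sum(axis=1)
    omega = D2.div(tot, axis=0)
    at_ideotype = tot == 0.0
    if at_ideotype.any():
        warnings.warn("genotype(s) exactly at the ideotype; omega set to uniform")
        omega.loc[at_ideotype, :] = 1.0 / D.shape[1]
    return MgidiResult(mgidi=mr.mgidi, ranks=mr.ranks, selected=mr.selected,
                       intensity=mr.intensity, n_selected=mr.n_selected,
                       distances=D, omega=omega)


def selection_differential_pct(xo: float, xs: float) -> float:
    """Percent selection differential: 100 * (Xs - Xo) / Xo."""
    if xo == 0:
        raise MetDataError("population mean is zero; SD% undefined")
    return 100.0 * (xs - xo) / xo


def assign_factors(fm: FactorModel) -> pd.Series:
    """Trait -> factor assignment by largest absolute rotated loading."""
    L = fm.loadings.abs().to_numpy()
    idx = np.argmax(L, axis=1)  # argmax takes the lower index on ties
    return pd.Series(idx + 1, index=fm.loadings.index)


def selection_gains(blups: BlupTable | pd.DataFrame, selected: list[str],
                    fm: FactorModel, specs: list[TraitSpec]
                    ) -> list[SelectionGainRow]:
    """Per-trait selection differentials of the selected set vs the population.

    Xo is the mean predicted value over all genotypes, Xs over the selected
    set; SD% = 100 (Xs - Xo)/Xo.  Each trait is attributed to the factor
    holding its largest absolute rotated loading, and the goal flag records
    whether the differential moved in the trait's desirable direction.
    """
    X = blups.values if isinstance(blups, BlupTable) else blups
    if not selected:
        raise MetDataError("empty selection")
    missing = set(selected) - set(X.index)
    if missing:
        raise MetDataError(f"selected ids not in table: {sorted(missing)}")
    by_name = {s.name: s for s in specs}
    factor_of = assign_factors(fm)
    rows = []
    for t in X.columns:
        xo = float(X[t].mean())
        xs = float(X.loc[selected, t].mean())
        sd = xs - xo
        sense = by_name[t].direction
        goal = sd >= 0 if sense == "increase" else sd <= 0
        rows.append(SelectionGainRow(
            trait=t, factor=int(factor_of[t]), sense=sense,
            xo=xo, xs=xs, sd=sd, sd_pct=selection_differential_pct(xo, xs),
            goal_met=bool(goal)))
    return rows


def cross_regime_overlap(selections: dict[str, list[str]]) -> dict:
    """Pairwise and full intersections of per-regime selected sets (tabular Venn)."""
    if len(selections) < 2:
        raise MetDataError("need selections from at least 2 regimes")
    regimes = list(selections)
    sets = {r: set(s) for r, s in selections.items()}
    pairwise = {}
    for i, a in enumerate(regimes):
        for b in regimes[i + 1:]:
            inter = sorted(sets[a] & sets[b])
            pairwise[f"{a}&{b}"] = {"members": inter, "count": len(inter)}
    full = sorted(set.intersection(*sets.values()))
    return {
        "per_regime": {r: {"members": sorted(sets[r]), "count": len(sets[r])}
                       for r in regimes},
        "pairwise": pairwise,
        "all": {"members": full, "count": len(full)},
    }
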