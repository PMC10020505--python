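"""Per-trait, per-regime linear mixed models by EM-REML.

Model, for one trait within one soil-moisture regime:

    y = X beta + Z u + eps,

fixed effects beta: intercept, environment, replicate-within-environment;
random effects u: genotype, genotype-x-environment (GEI), incomplete block
within replicate within environment; eps ~ N(0, sigma2_e I).  Variance
components are estimated by restricted maximum likelihood using the
expectation-maximization algorithm on the mixed-model equations (MME), whose
restricted log-likelihood is non-decreasing across iterations — this is
asserted at every step.

The restricted log-likelihood is evaluated from MME by-products via

    log|V| + log|X' V^-1 X| = (n - q - p) log sigma2_e
                              + sum_k q_k log sigma2_k + log|M|,

with M the MME coefficient matrix [[X'X, X'Z], [Z'X, Z'Z + sigma2_e G^-1]],
which avoids any n x n factorization.  A dense O(n^3) evaluation of the same
likelihood is kept in ``restricted_loglik_dense`` as an independent check.

Genetic parameters follow the genotype-mean basis: h2mg = sigma2_g /
(sigma2_g + sigma2_ge/e + sigma2_e/(e*b)); selection accuracy As = sqrt(h2mg);
R2ge = sigma2_ge / sigma2_p with sigma2_p = sigma2_g + sigma2_ge + sigma2_e
(incomplete-block variance excluded from the phenotypic total by convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .data import METDataset, MetDataError

__all__ = [
    "VarianceComponents",
    "GeneticParameters",
    "LRTResult",
    "ModelFit",
    "BlupTable",
    "fit_trait_model",
    "lrt_random_term",
    "genetic_parameters",
    "h2_genotype_mean",
    "blup_table",
    "restricted_loglik_dense",
]

RANDOM_TERMS = ("genotype", "gei", "block")

#: Variance estimates are clipped at this floor; estimates at the floor are
#: reported as exactly zero.
VARIANCE_FLOOR = 1e-10


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_block: float | None
    sigma2_e: float

    @property
    def sigma2_p(self) -> float:
        """Phenotypic variance: genotypic + GEI + residual (block excluded)."""
        return self.sigma2_g + self.sigma2_ge + self.sigma2_e


@dataclass
class GeneticParameters:
    h2mg: float
    accuracy: float
    r2ge: float
    cv_g: float
    cv_r: float
    cv_ratio: float
    env_f: float | None
    grand_mean: float


@dataclass
class LRTResult:
    term: str
    statistic: float
    df: int
    p_value: float


@dataclass
class ModelFit:
    trait: str
    regime: str
    beta: pd.Series
    u: dict[str, pd.Series]
    vc: VarianceComponents
    loglik: float
    loglik_history: list[float]
    n_iter: int
    converged: bool
    n_obs: int
    n_fixed: int
    q: dict[str, int]
    grand_mean: float
    fixed_mean: float
    cov_beta: pd.DataFrame
    env_coef_names: list[str]


@dataclass
class BlupTable:
    """Two-way table of predicted genotype means (genotype rows, trait cols)."""

    values: pd.DataFrame
    regime: str

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _dummies(codes: pd.Series, levels: list, drop_first: bool) -> np.ndarray:
    use = levels[1:] if drop_first else levels
    out = np.zeros((len(codes), len(use)))
    for j, lev in enumerate(use):
        out[:, j] = (codes == lev).to_numpy(float)
    return out


def build_design(ds: METDataset, trait: str, include_block: str | bool = "auto"):
    """Return y, X (full rank), Z term matrices and metadata for one trait.

    Rows with a missing plot value for the trait are dropped (the model
    consumes unbalanced data directly).  The incomplete-block random term is
    included only when some replicate actually contains more than one block;
    otherwise block is confounded with the fixed replicate effect.
    """
    df = ds.table.dropna(subset=[trait]).reset_index(drop=True)
    if df.empty:
        raise MetDataError(f"trait {trait!r} has no observations")
    if df["genotype"].nunique() < 2:
        raise MetDataError("need at least 2 genotypes")
    y = df[trait].to_numpy(float)

    envs = sorted(df["environment"].unique())
    # fixed: intercept + environment + replicate within environment
    X_cols = [np.ones((len(df), 1))]
    names = ["intercept"]
    env_names = [f"env[{e}]" for e in envs[1:]]
    X_cols.append(_dummies(df["environment"], envs, drop_first=True))
    names += env_names
    for e in envs:
        reps = sorted(df.loc[df["environment"] == e, "replicate"].unique())
        for r in reps[1:]:
            col = ((df["environment"] == e) & (df["replicate"] == r)).to_numpy(float)
            X_cols.append(col[:, None])
            names.append(f"rep[{e}:{r}]")
    X = np.hstack(X_cols)

    Z = {}
    levels = {}
    geno = sorted(df["genotype"].unique())
    Z["genotype"] = _dummies(df["genotype"], geno, drop_first=False)
    levels["genotype"] = geno
    if len(envs) > 1:
        ge = (df["genotype"] + "::" + df["environment"])
        ge_levels = sorted(ge.unique())
        Z["gei"] = _dummies(ge, ge_levels, drop_first=False)
        levels["gei"] = ge_levels

    blocks_per_rep = df.groupby(["environment", "replicate"])["block"].nunique()
    want_block = include_block if include_block != "auto" else bool((blocks_per_rep > 1).any())
    if want_block:
        blk = (df["environment"] + "::" + df["replicate"].astype(str) + "::" + df["block"].astype(str))
        blk_levels = sorted(blk.unique())
        Z["block"] = _dummies(blk, blk_levels, drop_first=False)
        levels["block"] = blk_levels

    return y, X, names, env_names, Z, levels, df


# ---------------------------------------------------------------------------
# EM-REML core
# ---------------------------------------------------------------------------

def _em_reml(y, X, Z, tol=1e-8, max_iter=500, floor=VARIANCE_FLOOR, start=None,
             accelerate=True):
    """EM-REML with an optional monotone SQUAREM safeguard.

    The plain EM map updates each component from the mixed-model-equation
    solution and prediction-error traces; it never decreases the restricted
    log-likelihood.  With ``accelerate=True`` a SQUAREM extrapolation (in
    log-variance space) is attempted each cycle and accepted only when it
    does not decrease the restricted log-likelihood, falling back to the
    plain EM iterate otherwise — monotonicity is preserved either way, and
    convergence near variance boundaries speeds up by orders of magnitude.
    ``max_iter`` counts applications of the EM map.
    """
    n = len(y)
    p = X.shape[1]
    terms = list(Z)
    q = {k: Z[k].shape[1] for k in terms}
    W = np.hstack([X] + [Z[k] for k in terms])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    offs = {}
    off = p
    for k in terms:
        offs[k] = (off, off + q[k])
        off += q[k]
    m = off
    eye_m = np.eye(m)
    nterm = len(terms)

    var_y = float(np.var(y)) if np.var(y) > 0 else 1.0
    if start is None:
        theta = np.full(nterm + 1, var_y / (nterm + 1))
    else:
        theta = np.array([max(start.get(k, var_y / 4), floor) for k in terms]
                         + [max(start.get("residual", var_y / 4), floor)])

    def em_step(theta):
        """One EM map application; returns (loglik at theta, next theta, state)."""
        s2, s2e = theta[:nterm], theta[nterm]
        M = WtW.copy()
        idx = np.arange(m)
        for j, k in enumerate(terms):
            a, bnd = offs[k]
            M[idx[a:bnd], idx[a:bnd]] += s2e / s2[j]
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        sol = linalg.cho_solve(cf, Wty, check_finite=False)
        logdetM = 2.0 * np.log(np.diag(cf[0])).sum()
        quad = (yty - sol @ Wty) / s2e
        # (n - m) = n - p - q_total, the coefficient of log sigma2_e
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + (n - m) * np.log(s2e)
                     + sum(q[k] * np.log(s2[j]) for j, k in enumerate(terms))
                     + logdetM + quad)
        Minv = linalg.cho_solve(cf, eye_m, check_finite=False)
        new = np.empty_like(theta)
        for j, k in enumerate(terms):
            a, bnd = offs[k]
            uk = sol[a:bnd]
            tr = np.trace(Minv[a:bnd, a:bnd])
            new[j] = max((uk @ uk + s2e * tr) / q[k], floor)
        new[nterm] = max((yty - sol @ Wty) / (n - p), floor)
        return ll, new, (sol, Minv)

    history: list[float] = []
    converged = False
    n_steps = 0
    ll_prev = -np.inf

    def record(ll):
        # guard is relative: ill-conditioned fits (sigma2_e -> 0) evaluate the
        # likelihood with O(1/sigma2_e) quadratic terms and lose precision
        if history and ll < history[-1] - 1e-6 * max(1.0, abs(history[-1])):
            raise RuntimeError(
                f"EM-REML restricted log-likelihood decreased "
                f"({history[-1]} -> {ll})")
        history.append(ll)

    state = None
    while n_steps < max_iter and not converged:
        ll0, theta1, state = em_step(theta)
        n_steps += 1
        record(ll0)
        if abs(ll0 - ll_prev) < tol:
            converged = True
            theta = theta  # current theta is the converged point
            break
        ll_prev = ll0
        if not accelerate:
            theta = theta1
            continue
        if n_steps >= max_iter:
            theta = theta1
            break
        ll1, theta2, state = em_step(theta1)
        n_steps += 1
        record(ll1)
        if abs(ll1 - ll0) < tol:
            theta = theta1
            ll_prev = ll1
            converged = True
            break
        ll_prev = ll1
        # SQUAREM S3 extrapolation in log-variance space
        lt0, lt1, lt2 = np.log(theta), np.log(theta1), np.log(theta2)
        r = lt1 - lt0
        v = (lt2 - lt1) - r
        nv = np.linalg.norm(v)
        if nv < 1e-14 or n_steps >= max_iter:
            theta = theta2
            continue
        alpha = -max(np.linalg.norm(r) / nv, 1.0)
        lcand = lt0 - 2.0 * alpha * r + (alpha ** 2) * v
        # keep the extrapolation within a sane band of the EM trajectory:
        # wild overshoots can make the MME matrix numerically singular
        lcand = np.clip(lcand, lt2 - 8.0, lt2 + 8.0)
        cand = np.maximum(np.exp(lcand), floor)
        try:
            ll_cand, theta3, cstate = em_step(cand)
        except np.linalg.LinAlgError:
            theta = theta2
            continue
        n_steps += 1
        if ll_cand >= ll1:          # monotone safeguard
            record(ll_cand)
            ll_prev = ll_cand
            theta = theta3
            state = cstate
        else:
            theta = theta2

    # final evaluation at the returned parameters (re-evaluation if the loop
    # already scored them; a fresh point if it stopped on the iteration cap)
    ll_fin, _, state = em_step(theta)
    if not history or ll_fin > history[-1]:
        record(ll_fin)
    sol, Minv = state
    s2 = {k: theta[j] for j, k in enumerate(terms)}
    s2e = theta[nterm]
    beta = sol[:p]
    u = {k: sol[offs[k][0]:offs[k][1]] for k in terms}
    cov_beta = s2e * Minv[:p, :p]
    return dict(s2=s2, s2e=s2e, beta=beta, u=u, loglik=ll_fin,
                history=history, n_iter=n_steps, converged=converged,
                cov_beta=cov_beta, n=n, p=p, q=q)


def restricted_loglik_dense(y, X, Z, s2, s2e):
    """Independent dense evaluation of the restricted log-likelihood.

    Builds V = sigma2_e I + sum_k sigma2_k Z_k Z_k' explicitly; O(n^3), used
    as an oracle to validate the MME-based evaluation and for optimizer
    cross-checks on small instances.
    """
    n, p = X.shape
    V = s2e * np.eye(n)
    for k, Zk in Z.items():
        V += s2[k] * (Zk @ Zk.T)
    cf = linalg.cho_factor(V, lower=True)
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    Vinv_y = linalg.cho_solve(cf, y)
    Vinv_X = linalg.cho_solve(cf, X)
    XtVinvX = X.T @ Vinv_X
    sign, logdetXVX = np.linalg.slogdet(XtVinvX)
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cf, r))
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetXVX + quad)


def fit_trait_model(ds: METDataset, trait: str, include_block="auto",
                    drop_terms: tuple[str, ...] = (), tol: float = 1e-8,
                    max_iter: int = 500, start: dict | None = None) -> ModelFit:
    """Fit the per-trait mixed model by EM-REML and return the full fit.

    ``drop_terms`` removes named random terms (used by the likelihood-ratio
    test for the reduced models).  Non-convergence within ``max_iter`` returns
    the fit with ``converged=False`` and emits a warning.
    """
    if trait not in ds.trait_names:
        raise MetDataError(f"trait {trait!r} not configured")
    y, X, names, env_names, Z, levels, df = build_design(ds, trait, include_block)
    for term in drop_terms:
        Z.pop(term, None)
    if not Z:
        raise MetDataError("model needs at least one random term")
    res = _em_reml(y, X, Z, tol=tol, max_iter=max_iter, start=start)
    if not res["converged"]:
        warnings.warn(f"EM-REML did not converge for trait {trait!r} "
                      f"in {max_iter} iterations")
    floor_zero = lambda v: 0.0 if v <= VARIANCE_FLOOR * 1.001 else v
    vc = VarianceComponents(
        sigma2_g=floor_zero(res["s2"].get("genotype", 0.0)),
        sigma2_ge=floor_zero(res["s2"].get("gei", 0.0)),
        sigma2_block=(floor_zero(res["s2"]["block"]) if "block" in res["s2"] else None),
        sigma2_e=res["s2e"],
    )
    regimes = df["regime"].unique()
    regime = regimes[0] if len(regimes) == 1 else "mixed"
    beta = pd.Series(res["beta"], index=names)
    u = {k: pd.Series(res["u"][k], index=levels[k]) for k in res["u"]}
    fixed_mean = float(np.mean(X @ res["beta"]))
    return ModelFit(
        trait=trait, regime=regime, beta=beta, u=u, vc=vc,
        loglik=res["loglik"], loglik_history=res["history"],
        n_iter=res["n_iter"], converged=res["converged"],
        n_obs=res["n"], n_fixed=res["p"], q=res["q"],
        grand_mean=float(np.mean(y)), fixed_mean=fixed_mean,
        cov_beta=pd.DataFrame(res["cov_beta"], index=names, columns=names),
        env_coef_names=env_names,
    )


def lrt_random_term(ds: METDataset, trait: str, term: str, boundary: bool = False,
                    full: ModelFit | None = None, **fit_kw) -> LRTResult:
    """Likelihood-ratio test for one random term (genotype or GEI).

    statistic = 2 (l_full - l_reduced), clipped at zero; the p-value comes
    from the upper tail of chi-square(1), or, with ``boundary=True``, from the
    half-and-half mixture 0.5 chi2(0) + 0.5 chi2(1) appropriate for a variance
    tested on the boundary of its parameter space.
    """
    if term not in ("genotype", "gei"):
        raise MetDataError(f"LRT term must be 'genotype' or 'gei', got {term!r}")
    if full is None:
        full = fit_trait_model(ds, trait, **fit_kw)
    if term not in full.u:
        raise MetDataError(f"term {term!r} absent from the full model")
    start = {"genotype": full.vc.sigma2_g or 0.1, "gei": full.vc.sigma2_ge or 0.1,
             "residual": full.vc.sigma2_e}
    if full.vc.sigma2_block is not None:
        start["block"] = full.vc.sigma2_block or 0.1
    start.pop(term, None)
    try:
        reduced = fit_trait_model(ds, trait, drop_terms=(term,),
                                  start=start, **fit_kw)
    except Exception as exc:  # pragma: no cover - defensive
        raise MetDataError(f"reduced model without {term!r} failed: {exc}") from exc
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if boundary:
        p = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    else:
        p = float(stats.chi2.sf(stat, 1))
    return LRTResult(term=term, statistic=stat, df=1, p_value=p)


def environment_f(fit: ModelFit) -> float | None:
    """Approximate Wald-type F statistic for the environment fixed effect."""
    if not fit.env_coef_names:
        return None
    idx = fit.env_coef_names
    b = fit.beta[idx].to_numpy()
    C = fit.cov_beta.loc[idx, idx].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(C, b)) / len(idx)
    except np.linalg.LinAlgError:
        return None
    return stat


def h2_genotype_mean(sigma2_g: float, sigma2_ge: float, sigma2_e: float,
                     e: int, b: int) -> float:
    """Broad-sense heritability on a genotype-mean basis.

    h2mg = sigma2_g / (sigma2_g + sigma2_ge/e + sigma2_e/(e*b)), where e is
    the number of environments and b the number of complete replicates per
    environment entering each genotype mean.
    """
    if e <= 0 or b <= 0:
        raise MetDataError("need e >= 1 environments and b >= 1 replicates")
    denom = sigma2_g + sigma2_ge / e + sigma2_e / (e * b)
    return sigma2_g / denom if denom > 0 else 0.0


def genetic_parameters(vc: VarianceComponents, ds: METDataset, trait: str,
                       fit: ModelFit | None = None) -> GeneticParameters:
    """Genotype-mean genetic parameters from variance components.

    h2mg divides sigma2_g by the variance of a genotype mean across e
    environments and b replicates: sigma2_g + sigma2_ge/e + sigma2_e/(e*b).
    """
    e, b = ds.e, ds.b
    if e == 0 or b == 0:
        raise MetDataError("need e >= 1 environments and b >= 1 replicates")
    mean = float(ds.table[trait].mean())
    if mean == 0:
        raise MetDataError("grand mean is zero; CV undefined")
    h2 = h2_genotype_mean(vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e, e, b)
    cv_g = 100.0 * np.sqrt(vc.sigma2_g) / mean
    cv_r = 100.0 * np.sqrt(vc.sigma2_e) / mean
    return GeneticParameters(
        h2mg=h2,
        accuracy=float(np.sqrt(h2)),
        r2ge=vc.sigma2_ge / vc.sigma2_p if vc.sigma2_p > 0 else 0.0,
        cv_g=cv_g,
        cv_r=cv_r,
        cv_ratio=cv_g / cv_r if cv_r > 0 else np.inf,
        env_f=environment_f(fit) if fit is not None else None,
        grand_mean=mean,
    )


def blup_table(fits: dict[str, ModelFit], ds: METDataset) -> BlupTable:
    """Two-way predicted genotype means: trait fixed-part mean + genotype BLUP.

    Every genotype present in the regime gets a row; every configured trait
    must have a fit.
    """
    missing = [t for t in ds.trait_names if t not in fits]
    if missing:
        raise MetDataError(f"missing fits for trait(s): {missing}")
    geno = ds.genotypes
    cols = {}
    for t in ds.trait_names:
        f = fits[t]
        blup = f.u["genotype"].reindex(geno).fillna(0.0)
        cols[t] = f.fixed_mean + blup
    regimes = ds.table["regime"].unique()
    regime = regimes[0] if len(regimes) == 1 else "mixed"
    return BlupTable(values=pd.DataFrame(cols, index=geno), regime=regime)
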