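"""Univariate polygenic variance-components models (ACE family).

The phenotypic variance of a quantitative trait measured on family members
is decomposed into additive genetic (A), common/household environmental (C)
and unique environmental (E) components. Within each family block the trait
vector is modelled as multivariate normal,

    y_b ~ N(X_b beta, 2 Phi_b sigma2_g + H_b sigma2_c + I sigma2_e),

where ``Phi_b`` holds kinship coefficients and ``H_b`` indicates shared
household. Narrow-sense heritability is ``h2 = sigma2_g / sigma2_p`` with
``sigma2_p = sigma2_g + sigma2_c + sigma2_e``.

Models are fitted by full maximum likelihood (fixed effects profiled out by
GLS), so nested models with identical fixed effects are comparable by
likelihood-ratio tests. Removing A or C pins a variance at its boundary, so
the corresponding LRT null is the 50:50 mixture of a point mass at zero and
a chi-square with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from ._gauss import (
    BlockSet,
    gather,
    loglik_at_beta,
    numerical_hessian,
    profiled_loglik,
)
from .pedigree import Pedigree

__all__ = [
    "VCModelSpec",
    "VCFit",
    "LRTResult",
    "chi2_pvalue",
    "mixture_pvalue",
    "vc_loglik",
    "fit_vc",
    "compare_models",
    "build_blockset",
]

_VAR_FLOOR_FRAC = 1e-8  # floor on sigma2_e, as a fraction of trait variance


@dataclass(frozen=True)
class VCModelSpec:
    """Which variance components to estimate; E is always present."""

    components: tuple[str, ...] = ("A", "E")
    trait: str = "trait"

    def __post_init__(self):
        if "E" not in self.components:
            raise ValueError("the unique-environment component E is mandatory")
        bad = set(self.components) - {"A", "C", "E"}
        if bad:
            raise ValueError(f"unknown components: {sorted(bad)}")


@dataclass
class VCFit:
    """Maximum-likelihood fit of one variance-components model."""

    components: tuple[str, ...]
    sigma2_g: float
    sigma2_c: float
    sigma2_e: float
    beta: np.ndarray | None
    loglik: float
    h2: float
    h2_se: float
    converged: bool
    n_used: int
    trait: str = "trait"
    n_blocks: int = 0

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_c + self.sigma2_e

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.loglik


@dataclass
class LRTResult:
    """Likelihood-ratio test with a plain or boundary-mixture null."""

    statistic: float
    null_kind: str  # "chi2_1" | "chi2_df" | "mixture_50_50"
    df: int
    p_value: float


def chi2_pvalue(statistic: float, df: int = 1) -> float:
    """Upper-tail chi-square p-value."""
    return float(stats.chi2.sf(max(statistic, 0.0), df))


def mixture_pvalue(statistic: float) -> float:
    """p under the 50:50 point-mass/chi2_1 mixture; statistic 0 gives 0.5."""
    return 0.5 * float(stats.chi2.sf(max(statistic, 0.0), 1))


def lrt_result(statistic: float, null_kind: str, df: int = 1) -> LRTResult:
    statistic = max(0.0, float(statistic))
    if null_kind == "mixture_50_50":
        p = mixture_pvalue(statistic)
    elif null_kind in ("chi2_1", "chi2_df"):
        p = chi2_pvalue(statistic, df)
    else:
        raise ValueError(f"unknown null kind: {null_kind!r}")
    return LRTResult(statistic=statistic, null_kind=null_kind, df=df, p_value=p)


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------


def build_blockset(
    ped: Pedigree, keep: np.ndarray | None = None
) -> tuple[BlockSet, np.ndarray]:
    """Group pedigree blocks over the rows flagged in ``keep``.

    Kinship submatrices are computed from the *full* pedigree before
    restriction, so dropping a connecting relative (e.g. an unphenotyped
    parent) preserves the relationships among the retained members.

    Returns the grouped :class:`BlockSet` and the kept pedigree positions in
    input order; the block index arrays refer to positions *within* that
    kept order.
    """
    n = len(ped)
    if keep is None:
        keep = np.ones(n, dtype=bool)
    kept = np.flatnonzero(keep)
    rank = np.full(n, -1, dtype=np.intp)
    rank[kept] = np.arange(kept.size)
    sexes = ped.sexes
    entries = []
    for block in ped.blocks:
        obs = block[keep[block]]
        if obs.size == 0:
            continue
        phi2 = 2.0 * ped.kinship(obs)
        entries.append((rank[obs], phi2, sexes[obs].astype(float)))
    return BlockSet(entries), kept


def _ace_sigmas(
    bs: BlockSet, sigma2_g: float, sigma2_c: float, sigma2_e: float
) -> list[np.ndarray]:
    out = []
    for g in bs.groups:
        k = g.phi2.shape[1]
        out.append(sigma2_g * g.phi2 + sigma2_c * g.house + sigma2_e * np.eye(k))
    return out


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------


def vc_loglik(
    sigma2_g: float,
    sigma2_c: float,
    sigma2_e: float,
    beta: np.ndarray | None,
    y: np.ndarray,
    X: np.ndarray | None,
    ped: Pedigree,
) -> float:
    """Exact block-diagonal Gaussian log-likelihood at the given parameters.

    Rows with missing trait (or covariate) values are excluded; returns
    ``-inf`` when the implied covariance is not positive definite.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    if X is not None:
        X = np.asarray(X, dtype=float)
        keep &= np.all(np.isfinite(X), axis=1)
    bs, kept = build_blockset(ped, keep)
    ys = gather(bs.groups, y[kept])
    xs = gather(bs.groups, X[kept]) if X is not None else None
    sig = _ace_sigmas(bs, sigma2_g, sigma2_c, sigma2_e)
    return loglik_at_beta(sig, ys, xs, beta)


def fit_vc(
    spec: VCModelSpec,
    y: np.ndarray,
    X: np.ndarray | None,
    ped: Pedigree,
    n_starts: int = 3,
    tol: float = 1e-10,
) -> VCFit:
    """Fit a polygenic model by maximum likelihood.

    Parameters
    ----------
    spec
        Components to estimate (always including E).
    y, X
        Trait vector and fixed-effect design aligned to pedigree order;
        ``X=None`` fits an intercept only. Rows with missing values drop.
    ped
        Pedigree supplying kinship and household structure.
    n_starts
        Deterministic multi-starts (environment-heavy, genetic-heavy,
        balanced splits of the trait variance), best kept.
    """
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((y.size, 1))
    X = np.asarray(X, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    bs, kept = build_blockset(ped, keep)
    yk, Xk = y[kept], X[kept]
    ys = gather(bs.groups, yk)
    xs = gather(bs.groups, Xk)

    if "A" in spec.components and not any(g.idx.shape[1] >= 2 for g in bs.groups):
        import warnings

        warnings.warn(
            "no family block has >= 2 phenotyped members; "
            "the genetic variance is unidentifiable",
            stacklevel=2,
        )

    resid = yk - Xk @ np.linalg.lstsq(Xk, yk, rcond=None)[0]
    v = max(float(resid.var()), 1e-12)
    floor = _VAR_FLOOR_FRAC * v

    has_a = "A" in spec.components
    has_c = "C" in spec.components
    free = [name for name, used in (("A", has_a), ("C", has_c)) if used] + ["E"]
    nf = len(free)

    def unpack(theta):
        g = theta[free.index("A")] if has_a else 0.0
        c = theta[free.index("C")] if has_c else 0.0
        return g, c, theta[-1]

    def negll(theta):
        g, c, e = unpack(theta)
        ll, _ = profiled_loglik(_ace_sigmas(bs, g, c, e), ys, xs)
        return -ll

    splits = {  # fractions of v assigned to each free component
        1: [(1.0,)],
        2: [(0.2, 0.8), (0.7, 0.3), (0.5, 0.5)],
        3: [(0.15, 0.1, 0.75), (0.6, 0.2, 0.2), (1 / 3, 1 / 3, 1 / 3)],
    }[nf][: max(1, n_starts)]
    bounds = [(0.0, None)] * (nf - 1) + [(floor, None)]

    best = None
    for frac in splits:
        x0 = np.array([f * v for f in frac])
        x0[-1] = max(x0[-1], floor)
        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = best.x
    g_hat, c_hat, e_hat = unpack(theta)
    ll, beta = profiled_loglik(_ace_sigmas(bs, g_hat, c_hat, e_hat), ys, xs)
    total = g_hat + c_hat + e_hat
    h2 = g_hat / total if total > 0 else 0.0

    h2_se = np.nan
    if has_a:
        h2_se = _h2_se(
            lambda th: -negll(th), theta, free, np.array([b[0] or 0.0 for b in bounds])
        )
    return VCFit(
        components=tuple(spec.components),
        sigma2_g=g_hat,
        sigma2_c=c_hat,
        sigma2_e=e_hat,
        beta=beta,
        loglik=float(ll),
        h2=float(h2),
        h2_se=float(h2_se),
        converged=bool(best.success),
        n_used=int(kept.size),
        trait=spec.trait,
        n_blocks=sum(g.idx.shape[0] for g in bs.groups),
    )


def _h2_se(loglik_fn, theta, free: Sequence[str], lower: np.ndarray) -> float:
    """Delta-method SE of h2 from the observed information of the profile
    likelihood in the free variance parameters."""
    hess = numerical_hessian(loglik_fn, theta, lower=lower)
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    total = float(np.sum(theta))
    if total <= 0:
        return np.nan
    # h2 = g / total; gradient wrt each free parameter
    g = theta[free.index("A")]
    grad = np.array(
        [(total - g) / total**2 if name == "A" else -g / total**2 for name in free]
    )
    var = float(grad @ cov @ grad)
    return np.sqrt(var) if var > 0 else np.nan


def compare_models(
    full: VCFit, nested: VCFit, null_kind: str | None = None
) -> LRTResult:
    """Likelihood-ratio test of a nested variance-components model.

    The null distribution defaults to the 50:50 mixture when exactly one
    boundary component (A or C) was removed, and to a plain chi-square with
    df equal to the number of removed components otherwise.
    """
    if full.n_used != nested.n_used:
        raise ValueError(
            f"fits use different data: n={full.n_used} vs {nested.n_used}"
        )
    removed = set(full.components) - set(nested.components)
    if not set(nested.components) <= set(full.components):
        raise ValueError("nested model is not a submodel of the full model")
    df = max(1, len(removed))
    if null_kind is None:
        null_kind = (
            "mixture_50_50"
            if len(removed) == 1 and removed <= {"A", "C"}
            else ("chi2_1" if df == 1 else "chi2_df")
        )
    stat = 2.0 * (full.loglik - nested.loglik)
    return lrt_result(stat, null_kind, df)
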