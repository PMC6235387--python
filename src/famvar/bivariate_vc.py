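"""Bivariate polygenic models: genetic correlation and pleiotropy.

Two traits measured on the same pedigree are modelled jointly. Each family
block contributes a multivariate-normal vector (individual-major, trait-minor
ordering) with covariance

    Sigma_b = 2 Phi_b (x) G + I (x) E,

where ``(x)`` is the Kronecker product, ``G`` the 2x2 additive-genetic
covariance matrix (variances sigma2_g1, sigma2_g2 and correlation rho_g)
and ``E`` the analogous unique-environment matrix with rho_e. A non-zero
genetic correlation rho_g indicates that a shared set of genes influences
both traits (pleiotropy). The implied phenotypic correlation is

    rho_p = rho_g sqrt(h2_1 h2_2) + rho_e sqrt((1 - h2_1)(1 - h2_2)).

Zero-value tests of rho_g, rho_e and rho_p compare the full fit against
maximum-likelihood refits under the constraint, using a plain chi-square(1)
null (the constraints are interior points of the parameter space). The
rho_p = 0 test constrains the nonlinear combination above, not a single
parameter, and is solved as an equality-constrained refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._gauss import BlockSet, profiled_loglik
from .pedigree import Pedigree
from .univariate_vc import LRTResult, build_blockset, lrt_result

__all__ = [
    "BivariateParams",
    "BivariateFit",
    "phenotypic_correlation",
    "bivariate_loglik",
    "fit_bivariate",
    "test_correlation",
]

_RHO_BOUND = 0.9999


@dataclass
class BivariateParams:
    sigma2_g1: float
    sigma2_g2: float
    sigma2_e1: float
    sigma2_e2: float
    rho_g: float
    rho_e: float
    beta1: np.ndarray | None = None
    beta2: np.ndarray | None = None


@dataclass
class BivariateFit:
    params: BivariateParams
    h2_1: float
    h2_2: float
    rho_p: float
    loglik: float
    converged: bool
    n_used: int
    constraint: str = "none"


def phenotypic_correlation(
    rho_g: float, rho_e: float, h2_1: float, h2_2: float
) -> float:
    """Phenotypic correlation implied by the bivariate decomposition."""
    for name, val in (("h2_1", h2_1), ("h2_2", h2_2)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [0, 1]")
    for name, val in (("rho_g", rho_g), ("rho_e", rho_e)):
        if not -1.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [-1, 1]")
    return rho_g * np.sqrt(h2_1 * h2_2) + rho_e * np.sqrt((1 - h2_1) * (1 - h2_2))


def _trait_matrices(p: BivariateParams) -> tuple[np.ndarray, np.ndarray]:
    gg = p.rho_g * np.sqrt(p.sigma2_g1 * p.sigma2_g2)
    ee = p.rho_e * np.sqrt(p.sigma2_e1 * p.sigma2_e2)
    G = np.array([[p.sigma2_g1, gg], [gg, p.sigma2_g2]])
    E = np.array([[p.sigma2_e1, ee], [ee, p.sigma2_e2]])
    return G, E


def _bivariate_sigmas(bs: BlockSet, G: np.ndarray, E: np.ndarray) -> list[np.ndarray]:
    out = []
    for g in bs.groups:
        nb, k = g.male.shape
        sig = np.einsum("bij,ts->bitjs", g.phi2, G).reshape(nb, 2 * k, 2 * k)
        sig = sig + np.kron(np.eye(k), E)
        out.append(sig)
    return out


def _stack_traits(bs: BlockSet, Y: np.ndarray, X: np.ndarray):
    """Interleave the two traits per individual and duplicate the design
    into per-trait coefficient slots."""
    p = X.shape[1]
    ys, xs = [], []
    for g in bs.groups:
        nb, k = g.idx.shape
        yb = Y[g.idx].reshape(nb, 2 * k)
        xb = np.zeros((nb, 2 * k, 2 * p))
        xg = X[g.idx]  # (nb, k, p)
        xb[:, 0::2, :p] = xg
        xb[:, 1::2, p:] = xg
        ys.append(yb)
        xs.append(xb)
    return ys, xs


def bivariate_loglik(
    params: BivariateParams,
    Y: np.ndarray,
    X: np.ndarray | None,
    ped: Pedigree,
) -> float:
    """Block-diagonal Gaussian log-likelihood of the bivariate model.

    ``Y`` is an (n, 2) trait matrix aligned to pedigree order; rows with any
    missing trait or covariate value are excluded (complete case). When
    ``params.beta1``/``beta2`` are ``None`` the mean is taken as zero.
    """
    Y = np.asarray(Y, dtype=float)
    if X is None:
        X = np.ones((Y.shape[0], 1))
    X = np.asarray(X, dtype=float)
    keep = np.all(np.isfinite(Y), axis=1) & np.all(np.isfinite(X), axis=1)
    bs, kept = build_blockset(ped, keep)
    ys, xs = _stack_traits(bs, Y[kept], X[kept])
    G, E = _trait_matrices(params)
    sig = _bivariate_sigmas(bs, G, E)
    if params.beta1 is None and params.beta2 is None:
        beta = None
    else:
        p = X.shape[1]
        b1 = params.beta1 if params.beta1 is not None else np.zeros(p)
        b2 = params.beta2 if params.beta2 is not None else np.zeros(p)
        beta = np.concatenate([b1, b2])
    from ._gauss import loglik_at_beta

    return loglik_at_beta(sig, ys, xs if beta is not None else None, beta)


_CONSTRAINTS = ("none", "rho_g_zero", "rho_e_zero", "rho_p_zero")


def fit_bivariate(
    ped: Pedigree,
    Y: np.ndarray,
    X: np.ndarray | None,
    constraint: str = "none",
    n_starts: int = 2,
    tol: float = 1e-10,
) -> BivariateFit:
    """Maximum-likelihood fit of the bivariate polygenic model.

    ``constraint`` fixes rho_g or rho_e to zero, or (for ``"rho_p_zero"``)
    refits under the nonlinear constraint that the implied phenotypic
    correlation vanishes.
    """
    if constraint not in _CONSTRAINTS:
        raise ValueError(f"unknown constraint {constraint!r}")
    Y = np.asarray(Y, dtype=float)
    if X is None:
        X = np.ones((Y.shape[0], 1))
    X = np.asarray(X, dtype=float)
    keep = np.all(np.isfinite(Y), axis=1) & np.all(np.isfinite(X), axis=1)
    bs, kept = build_blockset(ped, keep)
    Yk, Xk = Y[kept], X[kept]
    ys, xs = _stack_traits(bs, Yk, Xk)

    v = np.empty(2)
    for t in range(2):
        r = Yk[:, t] - Xk @ np.linalg.lstsq(Xk, Yk[:, t], rcond=None)[0]
        v[t] = max(float(r.var()), 1e-12)
    floor = 1e-8 * float(v.mean())

    fix_g = constraint == "rho_g_zero"
    fix_e = constraint == "rho_e_zero"

    def unpack(theta):
        s2g1, s2g2, s2e1, s2e2 = theta[:4]
        i = 4
        if fix_g:
            rg = 0.0
        else:
            rg = theta[i]
            i += 1
        re = 0.0 if fix_e else theta[i]
        return BivariateParams(s2g1, s2g2, s2e1, s2e2, rg, re)

    def negll(theta):
        G, E = _trait_matrices(unpack(theta))
        ll, _ = profiled_loglik(_bivariate_sigmas(bs, G, E), ys, xs)
        return -ll

    bounds = [(0.0, None), (0.0, None), (floor, None), (floor, None)]
    if not fix_g:
        bounds.append((-_RHO_BOUND, _RHO_BOUND))
    if not fix_e:
        bounds.append((-_RHO_BOUND, _RHO_BOUND))

    def start(gfrac):
        x0 = [gfrac * v[0], gfrac * v[1], (1 - gfrac) * v[0], (1 - gfrac) * v[1]]
        if not fix_g:
            x0.append(0.0)
        if not fix_e:
            x0.append(0.0)
        return np.array(x0)

    best = None
    for gf in [0.5, 0.2, 0.7][: max(1, n_starts)]:
        res = optimize.minimize(
            negll,
            start(gf),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    if constraint == "rho_p_zero":
        best = _refit_rho_p_zero(negll, unpack, best.x, bounds)

    pars = unpack(best.x)
    G, E = _trait_matrices(pars)
    ll, beta = profiled_loglik(_bivariate_sigmas(bs, G, E), ys, xs)
    p = Xk.shape[1]
    pars.beta1, pars.beta2 = (beta[:p], beta[p:]) if beta is not None else (None, None)
    h1 = pars.sigma2_g1 / max(pars.sigma2_g1 + pars.sigma2_e1, 1e-300)
    h2 = pars.sigma2_g2 / max(pars.sigma2_g2 + pars.sigma2_e2, 1e-300)
    rho_p = phenotypic_correlation(pars.rho_g, pars.rho_e, h1, h2)
    return BivariateFit(
        params=pars,
        h2_1=float(h1),
        h2_2=float(h2),
        rho_p=float(rho_p),
        loglik=float(ll),
        converged=bool(best.success),
        n_used=int(kept.size),
        constraint=constraint,
    )


def _implied_rho_p(pars: BivariateParams) -> float:
    h1 = pars.sigma2_g1 / max(pars.sigma2_g1 + pars.sigma2_e1, 1e-300)
    h2 = pars.sigma2_g2 / max(pars.sigma2_g2 + pars.sigma2_e2, 1e-300)
    return float(
        pars.rho_g * np.sqrt(h1 * h2) + pars.rho_e * np.sqrt((1 - h1) * (1 - h2))
    )


def _refit_rho_p_zero(negll, unpack, x_full, bounds):
    """Equality-constrained refit forcing the implied rho_p to zero."""
    cons = {"type": "eq", "fun": lambda th: _implied_rho_p(unpack(th))}
    best = None
    for x0 in (x_full, _project_rho_zero(x_full)):
        res = optimize.minimize(
            negll,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=[cons],
            options={"ftol": 1e-12, "maxiter": 500},
        )
        if abs(cons["fun"](res.x)) > 1e-6:
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:  # fall back to both correlations at zero
        x0 = _project_rho_zero(x_full)
        best = optimize.minimize(
            negll,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=[cons],
            options={"ftol": 1e-10, "maxiter": 500},
        )
    return best


def _project_rho_zero(x):
    x = np.array(x, dtype=float)
    x[4:] = 0.0
    return x


def test_correlation(
    ped: Pedigree,
    Y: np.ndarray,
    X: np.ndarray | None,
    which: str,
    n_starts: int = 2,
) -> tuple[LRTResult, float]:
    """Zero-value LRT for one of the three correlations.

    Returns the test (plain chi-square(1) null) and the unconstrained
    estimate of the tested correlation.
    """
    mapping = {"rho_g": "rho_g_zero", "rho_e": "rho_e_zero", "rho_p": "rho_p_zero"}
    if which not in mapping:
        raise ValueError(f"which must be one of {sorted(mapping)}")
    full = fit_bivariate(ped, Y, X, constraint="none", n_starts=n_starts)
    nested = fit_bivariate(ped, Y, X, constraint=mapping[which], n_starts=n_starts)
    stat = 2.0 * (full.loglik - nested.loglik)
    est = {
        "rho_g": full.params.rho_g,
        "rho_e": full.params.rho_e,
        "rho_p": full.rho_p,
    }[which]
    return lrt_result(stat, "chi2_1"), float(est)
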