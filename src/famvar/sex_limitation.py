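"""Sex-limitation (genotype-by-sex interaction) polygenic models.

The additive genetic variance is allowed to differ between the sexes
(sigma_gM, sigma_gF), as is the unique environmental variance (sigma_eM,
sigma_eF), and the genetic effects expressed in males and females may be
imperfectly correlated (rho_gMF). Genetic covariances between relatives are

    cov(M1, M2) = 2 phi sigma_gM^2
    cov(F1, F2) = 2 phi sigma_gF^2
    cov(M, F)   = 2 phi sigma_gM sigma_gF rho_gMF

with the unique environment contributing only on the diagonal. Evidence for
a genotype-by-sex interaction comes from likelihood-ratio tests of the two
constraints: rho_gMF = 1 (same genes act in both sexes) and
sigma_gM = sigma_gF (same magnitude of genetic influence). The former pins
rho_gMF at its upper bound, so its LRT null is the 50:50 mixture of a point
mass at zero and chi-square(1); the latter is an interior constraint tested
against a plain chi-square(1).

rho_gMF is estimated on [0, 1] by default; identification requires at least
one phenotyped opposite-sex relative pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._gauss import BlockSet, gather, profiled_loglik
from .pedigree import Pedigree
from .univariate_vc import LRTResult, build_blockset, lrt_result

__all__ = [
    "GxSParams",
    "GxSFit",
    "gxs_covariance",
    "gxs_loglik",
    "fit_gxs",
    "test_gxs",
]

CONSTRAINTS = ("none", "rho_eq_1", "sigma_g_equal")


@dataclass
class GxSParams:
    """Sex-specific standard deviations and the cross-sex genetic correlation."""

    sigma_gM: float
    sigma_gF: float
    sigma_eM: float
    sigma_eF: float
    rho_gMF: float
    beta: np.ndarray | None = None


@dataclass
class GxSFit:
    params: GxSParams
    loglik: float
    constraint: str
    converged: bool
    n_used: int

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.loglik


def gxs_covariance(
    sex_i: str,
    sex_j: str,
    phi_ij: float,
    same_individual: bool,
    params: GxSParams,
) -> float:
    """One entry of the sex-limitation covariance matrix.

    ``sex_i``/``sex_j`` are ``"male"``/``"female"``; ``phi_ij`` is the
    kinship coefficient (0.5 on the diagonal for non-inbred individuals).
    """
    g_i = params.sigma_gM if sex_i == "male" else params.sigma_gF
    g_j = params.sigma_gM if sex_j == "male" else params.sigma_gF
    rho = 1.0 if sex_i == sex_j else params.rho_gMF
    cov = 2.0 * phi_ij * g_i * g_j * rho
    if same_individual:
        e = params.sigma_eM if sex_i == "male" else params.sigma_eF
        cov += e * e
    return cov


def _gxs_sigmas(
    bs: BlockSet,
    s2_gm: float,
    s2_gf: float,
    s2_em: float,
    s2_ef: float,
    rho: float,
) -> list[np.ndarray]:
    out = []
    for g in bs.groups:
        male = g.male  # (nb, k)
        sd = np.where(male > 0.5, np.sqrt(s2_gm), np.sqrt(s2_gf))
        opp = male[:, :, None] != male[:, None, :]
        corr = np.where(opp, rho, 1.0)
        sig = g.phi2 * sd[:, :, None] * sd[:, None, :] * corr
        e2 = np.where(male > 0.5, s2_em, s2_ef)
        k = male.shape[1]
        sig = sig + e2[:, :, None] * np.eye(k)
        out.append(sig)
    return out


def gxs_loglik(
    params: GxSParams,
    y: np.ndarray,
    X: np.ndarray | None,
    ped: Pedigree,
) -> float:
    """Block-diagonal Gaussian log-likelihood at the given parameters.

    Uses ``params.beta`` when set (zero mean otherwise); rows with missing
    values are excluded. Returns ``-inf`` on a non-positive-definite
    covariance.
    """
    from ._gauss import loglik_at_beta

    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    if X is not None:
        X = np.asarray(X, dtype=float)
        keep &= np.all(np.isfinite(X), axis=1)
    bs, kept = build_blockset(ped, keep)
    ys = gather(bs.groups, y[kept])
    xs = gather(bs.groups, X[kept]) if X is not None else None
    sig = _gxs_sigmas(
        bs,
        params.sigma_gM**2,
        params.sigma_gF**2,
        params.sigma_eM**2,
        params.sigma_eF**2,
        params.rho_gMF,
    )
    beta = params.beta if X is not None else None
    return loglik_at_beta(sig, ys, xs if beta is not None else None, beta)


def fit_gxs(
    ped: Pedigree,
    y: np.ndarray,
    X: np.ndarray | None,
    constraint: str = "none",
    rho_bounds: tuple[float, float] = (0.0, 1.0),
    n_starts: int = 3,
    tol: float = 1e-10,
) -> GxSFit:
    """Maximum-likelihood fit of the sex-limitation model.

    ``constraint`` selects the full model (``"none"``) or one of the nested
    models ``"rho_eq_1"`` / ``"sigma_g_equal"``. Sex is taken from the
    pedigree; the design ``X`` should include sex as a fixed effect so that
    mean differences between the sexes are absorbed.
    """
    if constraint not in CONSTRAINTS:
        raise ValueError(f"unknown constraint {constraint!r}")
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((y.size, 1))
    X = np.asarray(X, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    bs, kept = build_blockset(ped, keep)
    yk, Xk = y[kept], X[kept]
    ys = gather(bs.groups, yk)
    xs = gather(bs.groups, Xk)

    male_any = any(g.male.any() for g in bs.groups)
    female_any = any((1 - g.male).any() for g in bs.groups)
    if not (male_any and female_any):
        raise ValueError("sex-limitation model requires both sexes in the sample")
    has_opp_pair = any(
        bool(
            np.any(
                (g.male[:, :, None] != g.male[:, None, :])
                & (g.phi2 > 0)
                & ~np.eye(g.male.shape[1], dtype=bool)
            )
        )
        for g in bs.groups
    )
    if constraint != "rho_eq_1" and not has_opp_pair:
        warnings.warn(
            "no phenotyped opposite-sex relative pair: rho_gMF is unidentified",
            stacklevel=2,
        )

    resid = yk - Xk @ np.linalg.lstsq(Xk, yk, rcond=None)[0]
    v = max(float(resid.var()), 1e-12)
    floor = 1e-8 * v

    equal_g = constraint == "sigma_g_equal"
    fixed_rho = constraint == "rho_eq_1"

    def unpack(theta):
        i = 0
        if equal_g:
            s2_gm = s2_gf = theta[i]
            i += 1
        else:
            s2_gm, s2_gf = theta[i], theta[i + 1]
            i += 2
        s2_em, s2_ef = theta[i], theta[i + 1]
        i += 2
        rho = 1.0 if fixed_rho else theta[i]
        return s2_gm, s2_gf, s2_em, s2_ef, rho

    def negll(theta):
        ll, _ = profiled_loglik(_gxs_sigmas(bs, *unpack(theta)), ys, xs)
        return -ll

    n_g = 1 if equal_g else 2
    bounds = [(0.0, None)] * n_g + [(floor, None)] * 2
    if not fixed_rho:
        bounds.append(rho_bounds)

    g_fracs = [0.2, 0.6, 0.4][: max(1, n_starts)]
    best = None
    for gf in g_fracs:
        x0 = [gf * v] * n_g + [(1 - gf) * v] * 2
        if not fixed_rho:
            x0.append(np.clip(0.9, *rho_bounds))
        res = optimize.minimize(
            negll,
            np.array(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 800},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    s2_gm, s2_gf, s2_em, s2_ef, rho = unpack(best.x)
    ll, beta = profiled_loglik(_gxs_sigmas(bs, s2_gm, s2_gf, s2_em, s2_ef, rho), ys, xs)
    params = GxSParams(
        sigma_gM=float(np.sqrt(s2_gm)),
        sigma_gF=float(np.sqrt(s2_gf)),
        sigma_eM=float(np.sqrt(s2_em)),
        sigma_eF=float(np.sqrt(s2_ef)),
        rho_gMF=float(rho),
        beta=beta,
    )
    return GxSFit(
        params=params,
        loglik=float(ll),
        constraint=constraint,
        converged=bool(best.success),
        n_used=int(kept.size),
    )


def test_gxs(full: GxSFit, nested: GxSFit) -> LRTResult:
    """LRT of a constrained sex-limitation model against the full model.

    Negative differences within optimiser tolerance are clamped to zero;
    ``rho_eq_1`` uses the boundary mixture null, ``sigma_g_equal`` a plain
    chi-square(1).
    """
    if full.constraint != "none":
        raise ValueError("first argument must be the unconstrained fit")
    if nested.constraint == "none":
        raise ValueError("second argument must be a constrained fit")
    if full.n_used != nested.n_used:
        raise ValueError("fits use different data")
    stat = 2.0 * (full.loglik - nested.loglik)
    null = "mixture_50_50" if nested.constraint == "rho_eq_1" else "chi2_1"
    return lrt_result(stat, null)
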