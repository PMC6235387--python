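"""Block-diagonal multivariate-normal likelihood machinery.

Family studies give a covariance matrix that is block-diagonal over family
blocks. All fitters in this package reduce to maximising

    loglik(theta, beta) = sum_b log N(y_b | X_b beta, Sigma_b(theta))

over variance parameters ``theta`` with the fixed effects ``beta`` profiled
out by GLS. Blocks of equal dimension are stacked into 3-d arrays so each
likelihood evaluation is a handful of batched ``numpy.linalg`` calls rather
than a Python loop over ~1000 families.

Non-positive-definite ``Sigma`` is a defined failure: functions return
``-inf`` (never raise), which bounded optimisers treat as a rejected step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SizeGroup:
    """All blocks of one common dimension, stacked."""

    idx: np.ndarray  # (nb, k) positions into the full data vectors
    phi2: np.ndarray  # (nb, k, k) additive relationship 2*phi
    house: np.ndarray  # (nb, k, k) household-sharing indicator
    male: np.ndarray  # (nb, k) 1 = male, 0 = female


class BlockSet:
    """Grouped view of pedigree blocks restricted to analysed rows.

    Parameters
    ----------
    blocks : sequence of (index_array, phi2_block, male_block)
        One entry per family block, already restricted to rows with
        complete data. ``index_array`` maps into the analysed-data order.
    """

    def __init__(self, blocks: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]]):
        by_size: dict[int, list] = {}
        for idx, phi2, male in blocks:
            by_size.setdefault(len(idx), []).append((idx, phi2, male))
        self.groups: list[SizeGroup] = []
        self.n_obs = 0
        for k in sorted(by_size):
            if k == 0:
                continue
            items = by_size[k]
            idx = np.stack([it[0] for it in items])
            phi2 = np.stack([it[1] for it in items])
            male = np.stack([it[2] for it in items])
            self.groups.append(
                SizeGroup(idx=idx, phi2=phi2, house=np.ones_like(phi2), male=male)
            )
            self.n_obs += idx.size


def _chol(sigma: np.ndarray) -> np.ndarray | None:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return None


def profiled_loglik(
    sigmas: list[np.ndarray],
    ys: list[np.ndarray],
    xs: list[np.ndarray] | None,
) -> tuple[float, np.ndarray | None]:
    """Gaussian log-likelihood with the mean coefficients profiled out.

    Parameters
    ----------
    sigmas
        Per size-group covariance stacks, shape ``(nb, k, k)``.
    ys
        Per-group response stacks, shape ``(nb, k)``.
    xs
        Per-group design stacks ``(nb, k, p)``, or ``None`` for a known
        zero mean.

    Returns
    -------
    (loglik, beta_hat); ``(-inf, None)`` if any block covariance is not
    positive definite.
    """
    logdet = 0.0
    ytsiy = 0.0
    n_total = 0
    p = xs[0].shape[2] if xs is not None else 0
    xtsix = np.zeros((p, p))
    xtsiy = np.zeros(p)
    for g, (sigma, y) in enumerate(zip(sigmas, ys)):
        chol = _chol(sigma)
        if chol is None:
            return -np.inf, None
        d = np.diagonal(chol, axis1=1, axis2=2)
        if np.any(d <= 0):
            return -np.inf, None
        logdet += 2.0 * float(np.log(d).sum())
        w = np.linalg.solve(chol, y[..., None])[..., 0]  # (nb, k)
        ytsiy += float((w * w).sum())
        n_total += y.size
        if p:
            z = np.linalg.solve(chol, xs[g])  # (nb, k, p)
            xtsix += np.einsum("bkp,bkq->pq", z, z)
            xtsiy += np.einsum("bkp,bk->p", z, w)
    if p:
        try:
            beta = np.linalg.solve(xtsix, xtsiy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(xtsix, xtsiy, rcond=None)[0]
        quad = ytsiy - float(xtsiy @ beta)
    else:
        beta, quad = None, ytsiy
    ll = -0.5 * (n_total * _LOG2PI + logdet + quad)
    return ll, beta


def loglik_at_beta(
    sigmas: list[np.ndarray],
    ys: list[np.ndarray],
    xs: list[np.ndarray] | None,
    beta: np.ndarray | None,
) -> float:
    """Gaussian log-likelihood at fixed mean coefficients ``beta``."""
    ll = 0.0
    for g, (sigma, y) in enumerate(zip(sigmas, ys)):
        r = y if xs is None or beta is None else y - xs[g] @ beta
        chol = _chol(sigma)
        if chol is None:
            return -np.inf
        d = np.diagonal(chol, axis1=1, axis2=2)
        if np.any(d <= 0):
            return -np.inf
        w = np.linalg.solve(chol, r[..., None])[..., 0]
        ll += -0.5 * (
            r.size * _LOG2PI + 2.0 * float(np.log(d).sum()) + float((w * w).sum())
        )
    return ll


def gather(groups: Sequence[SizeGroup], values: np.ndarray) -> list[np.ndarray]:
    """Slice a 1-d (or 2-d row-wise) data array into per-group stacks."""
    return [values[g.idx] for g in groups]


def numerical_hessian(
    fun: Callable[[np.ndarray], float],
    x: np.ndarray,
    lower: np.ndarray | None = None,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central-difference Hessian; steps shrink to stay above ``lower``."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    if lower is not None:
        # keep x - h (and x - 2h in cross terms) inside the feasible box
        room = (x - lower) / 2.0
        h = np.where(room > 0, np.minimum(h, np.maximum(room, 1e-12)), h)
    hess = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fij = fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(
                x - ei - ej
            )
            hess[i, j] = hess[j, i] = fij / (4.0 * h[i] * h[j])
    return hess
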