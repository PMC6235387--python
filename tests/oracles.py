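"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: kinship is
estimated by gene-dropping Monte Carlo (allele transmission simulation),
and Gaussian log-densities come from a dense covariance assembled entry by
entry and evaluated with scipy's generic multivariate-normal logpdf.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from famvar.pedigree import Individual, Pedigree


def _topo_positions(ped: Pedigree) -> list[int]:
    """Parents-before-children ordering computed from the raw records."""
    pos = {ind.id: k for k, ind in enumerate(ped.individuals)}
    remaining = set(range(len(ped.individuals)))
    order: list[int] = []
    placed: set[int] = set()
    while remaining:
        progressed = False
        for k in sorted(remaining):
            ind = ped.individuals[k]
            parents = [pos[p] for p in (ind.father_id, ind.mother_id) if p]
            if all(p in placed for p in parents):
                order.append(k)
                placed.add(k)
                remaining.discard(k)
                progressed = True
        assert progressed, "cyclic pedigree handed to oracle"
    return order


def gene_drop_kinship(
    ped: Pedigree, n_rep: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo kinship: simulate allele transmission, count IBD sharing.

    Returns (phi_hat, phi_se) in pedigree input order. Each founder (and
    each unknown parent) contributes two globally unique allele labels;
    children inherit one allele from each known parent uniformly at random.
    phi(i, j) is the probability that one allele drawn from i matches one
    drawn from j by descent.
    """
    rng = np.random.default_rng(seed)
    pos = {ind.id: k for k, ind in enumerate(ped.individuals)}
    next_label = [0]

    def fresh() -> np.ndarray:
        next_label[0] += 1
        return np.full(n_rep, next_label[0], dtype=np.int64)

    alleles: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in _topo_positions(ped):
        ind = ped.individuals[k]
        pair = []
        for pid in (ind.father_id, ind.mother_id):
            if pid is None:
                pair.append(fresh())
            else:
                pa, pb = alleles[pos[pid]]
                pick = rng.integers(0, 2, n_rep).astype(bool)
                pair.append(np.where(pick, pa, pb))
        alleles[k] = (pair[0], pair[1])

    n = len(ped.individuals)
    phi = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        ai, bi = alleles[i]
        for j in range(i, n):
            aj, bj = alleles[j]
            share = (
                (ai == aj).astype(float)
                + (ai == bj)
                + (bi == aj)
                + (bi == bj)
            ) / 4.0
            phi[i, j] = phi[j, i] = share.mean()
            se[i, j] = se[j, i] = share.std(ddof=1) / np.sqrt(n_rep)
    return phi, se


def random_pedigree(rng: np.random.Generator, max_size: int = 8) -> Pedigree:
    """Random acyclic pedigree: founders plus children of earlier members."""
    size = int(rng.integers(2, max_size + 1))
    inds: list[Individual] = []
    males: list[str] = []
    females: list[str] = []
    for k in range(size):
        iid = f"I{k}"
        sex = "male" if rng.random() < 0.5 else "female"
        father = mother = None
        if inds and rng.random() < 0.7:
            if males and rng.random() < 0.8:
                father = str(rng.choice(males))
            if females and rng.random() < 0.8:
                mother = str(rng.choice(females))
        inds.append(Individual(iid, "FAM", father, mother, sex))
        (males if sex == "male" else females).append(iid)
    return Pedigree(inds)


def dense_mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Generic dense multivariate-normal log-density."""
    return float(
        stats.multivariate_normal.logpdf(y, mean=mean, cov=cov, allow_singular=False)
    )


def dense_univariate_cov(
    phi: np.ndarray, s2g: float, s2c: float, s2e: float
) -> np.ndarray:
    """Entry-by-entry ACE covariance (no vectorised construction)."""
    k = phi.shape[0]
    cov = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            cov[i, j] = 2.0 * phi[i, j] * s2g + s2c
            if i == j:
                cov[i, j] += s2e
    return cov


def dense_gxs_cov(phi, male, s_gm, s_gf, s_em, s_ef, rho) -> np.ndarray:
    k = phi.shape[0]
    cov = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            gi = s_gm if male[i] else s_gf
            gj = s_gm if male[j] else s_gf
            r = 1.0 if male[i] == male[j] else rho
            cov[i, j] = 2.0 * phi[i, j] * gi * gj * r
            if i == j:
                e = s_em if male[i] else s_ef
                cov[i, j] += e * e
    return cov


def dense_bivariate_cov(phi, s2g, s2e, rho_g, rho_e) -> np.ndarray:
    """4-entry-per-pair Kronecker construction, individual-major order."""
    k = phi.shape[0]
    cov = np.empty((2 * k, 2 * k))
    gg = rho_g * np.sqrt(s2g[0] * s2g[1])
    ee = rho_e * np.sqrt(s2e[0] * s2e[1])
    G = [[s2g[0], gg], [gg, s2g[1]]]
    E = [[s2e[0], ee], [ee, s2e[1]]]
    for i in range(k):
        for j in range(k):
            for t in range(2):
                for s in range(2):
                    val = 2.0 * phi[i, j] * G[t][s]
                    if i == j:
                        val += E[t][s]
                    cov[2 * i + t, 2 * j + s] = val
    return cov
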