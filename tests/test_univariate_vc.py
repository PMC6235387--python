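"""Univariate ACE likelihood, fitting, and likelihood-ratio machinery."""

import numpy as np
import pytest

from famvar.pedigree import Individual, Pedigree
from famvar.univariate_vc import (
    VCFit,
    VCModelSpec,
    chi2_pvalue,
    compare_models,
    fit_vc,
    mixture_pvalue,
    vc_loglik,
)
from famvar.synthetic_data import SimulationScenario, simulate_dataset

from conftest import aligned, basic_design
from oracles import dense_mvn_loglik, dense_univariate_cov, random_pedigree


def _singleton():
    return Pedigree([Individual("A", "f", None, None, "male")])


class TestLoglik:
    def test_single_standard_normal(self):
        ped = _singleton()
        ll = vc_loglik(0.0, 0.0, 1.0, np.array([0.0]), np.array([0.0]),
                       np.ones((1, 1)), ped)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_sib_pair_matches_dense_oracle(self, sib_quartet):
        # phenotyped sibs only; parents unobserved
        y = np.array([np.nan, np.nan, 0.3, -0.8])
        ll = vc_loglik(0.6, 0.0, 0.4, None, y, None, sib_quartet)
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert ll == pytest.approx(
            dense_mvn_loglik(np.array([0.3, -0.8]), np.zeros(2), cov), abs=1e-10
        )

    def test_additivity_over_blocks(self, trio):
        rng = np.random.default_rng(0)
        y1 = rng.standard_normal(3)
        two = Pedigree(
            [
                Individual("F", "a", None, None, "male"),
                Individual("M", "a", None, None, "female"),
                Individual("C", "a", "F", "M", "male"),
                Individual("F2", "b", None, None, "male"),
                Individual("M2", "b", None, None, "female"),
                Individual("C2", "b", "F2", "M2", "male"),
            ]
        )
        y2 = rng.standard_normal(3)
        args = (0.5, 0.2, 0.6)
        ll_sum = vc_loglik(*args, None, y1, None, trio) + vc_loglik(
            *args, None, y2, None, trio
        )
        ll_joint = vc_loglik(*args, None, np.concatenate([y1, y2]), None, two)
        assert ll_joint == pytest.approx(ll_sum, abs=1e-10)

    def test_non_positive_definite_returns_neg_inf(self, trio):
        y = np.zeros(3)
        assert vc_loglik(0.0, 0.0, 0.0, None, y, None, trio) == -np.inf

    def test_matches_dense_oracle_on_random_pedigrees(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            ped = random_pedigree(rng, max_size=8)
            n = len(ped)
            y = rng.standard_normal(n)
            beta = rng.standard_normal(2)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            s2g, s2c, s2e = rng.uniform(0.1, 1.0, 3)
            ll = vc_loglik(s2g, s2c, s2e, beta, y, X, ped)
            cov = dense_univariate_cov(ped.kinship(), s2g, s2c, s2e)
            ref = dense_mvn_loglik(y, X @ beta, cov)
            assert ll == pytest.approx(ref, abs=1e-8)


class TestFit:
    def test_e_only_closed_form(self):
        rng = np.random.default_rng(1)
        inds = []
        for f in range(60):
            inds.append(Individual(f"I{f}", f"f{f}", None, None, "male"))
        ped = Pedigree(inds)
        n = len(ped)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, -2.0]) + rng.standard_normal(n)
        fit = fit_vc(VCModelSpec(("E",)), y, X, ped)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta_ols) ** 2).sum())
        assert fit.sigma2_e == pytest.approx(rss / n, rel=1e-5)
        assert fit.beta == pytest.approx(beta_ols, rel=1e-6)

    @staticmethod
    def _sim(h2, seed, n_families=300):
        scenario = SimulationScenario(
            name="t",
            n_families=n_families,
            model="univariate_ace",
            params={"h2": h2},
            trait_transform="identity",
        )
        ds = simulate_dataset(scenario, seed)
        return ds, aligned(ds, "tsh"), basic_design(ds)

    def test_recovers_moderate_heritability(self):
        h2s = []
        for s in range(8):
            ds, y, X = self._sim(0.54, s)
            fit = fit_vc(VCModelSpec(("A", "E")), y, X, ds.pedigree)
            assert fit.converged
            h2s.append(fit.h2)
        assert abs(np.mean(h2s) - 0.54) < 0.08

    def test_zero_heritability_hits_boundary(self):
        h2s = []
        for s in range(10):
            ds, y, X = self._sim(0.0, s, n_families=200)
            fit = fit_vc(VCModelSpec(("A", "E")), y, X, ds.pedigree)
            h2s.append(fit.h2)
        assert np.median(h2s) < 0.05

    def test_affine_rescaling(self):
        ds, y, X = self._sim(0.5, 3, n_families=150)
        base = fit_vc(VCModelSpec(("A", "E")), y, X, ds.pedigree)
        scaled = fit_vc(VCModelSpec(("A", "E")), 3.0 * y + 7.0, X, ds.pedigree)
        assert scaled.h2 == pytest.approx(base.h2, abs=1e-5)
        assert scaled.sigma2_g == pytest.approx(9.0 * base.sigma2_g, rel=1e-3)

    def test_block_order_invariance(self):
        ds, y, X = self._sim(0.5, 4, n_families=80)
        base = fit_vc(VCModelSpec(("A", "E")), y, X, ds.pedigree)
        perm_blocks = list(reversed(ds.pedigree.blocks))
        order = np.concatenate(perm_blocks)
        ped2 = Pedigree([ds.pedigree.individuals[i] for i in order])
        fit2 = fit_vc(VCModelSpec(("A", "E")), y[order], X[order], ped2)
        assert fit2.loglik == pytest.approx(base.loglik, abs=1e-6)
        assert fit2.h2 == pytest.approx(base.h2, abs=1e-5)

    def test_singleton_only_pedigree_warns(self):
        ped = Pedigree(
            [
                Individual("A", "f1", None, None, "male"),
                Individual("B", "f2", None, None, "female"),
                Individual("C", "f3", None, None, "male"),
            ]
        )
        y = np.array([0.1, -0.2, 0.4])
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit_vc(VCModelSpec(("A", "E")), y, None, ped)


class TestLRT:
    def _fit(self, loglik, components=("A", "E"), n=100):
        return VCFit(
            components=components,
            sigma2_g=0.5,
            sigma2_c=0.0,
            sigma2_e=0.5,
            beta=None,
            loglik=loglik,
            h2=0.5,
            h2_se=0.1,
            converged=True,
            n_used=n,
        )

    def test_zero_statistic(self):
        full = self._fit(-100.0, ("A", "C", "E"))
        nested = self._fit(-100.0, ("A", "E"))
        res = compare_models(full, nested)
        assert res.statistic == 0.0
        assert res.null_kind == "mixture_50_50"
        assert res.p_value == pytest.approx(0.5)
        plain = compare_models(full, nested, null_kind="chi2_1")
        assert plain.p_value == pytest.approx(1.0)

    def test_negative_difference_clamped(self):
        full = self._fit(-100.0, ("A", "C", "E"))
        nested = self._fit(-99.9999, ("A", "E"))
        assert compare_models(full, nested).statistic == 0.0

    @pytest.mark.parametrize(
        "stat,expected",
        [(4.35, 0.037), (5.03, 0.025), (0.93, 0.335), (2.706, 0.100)],
    )
    def test_chi2_tail_values(self, stat, expected):
        assert chi2_pvalue(stat, 1) == pytest.approx(expected, abs=5e-4)

    def test_mixture_halves_the_tail(self):
        assert mixture_pvalue(4.35) == pytest.approx(0.5 * chi2_pvalue(4.35, 1))

    def test_mismatched_n_raises(self):
        full = self._fit(-10.0, ("A", "C", "E"), n=100)
        nested = self._fit(-11.0, ("A", "E"), n=90)
        with pytest.raises(ValueError):
            compare_models(full, nested)

    def test_two_df_removal_uses_plain_chi2(self):
        full = self._fit(-10.0, ("A", "C", "E"))
        nested = self._fit(-13.0, ("E",))
        res = compare_models(full, nested)
        assert res.df == 2 and res.null_kind == "chi2_df"
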