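"""Derived variables, exclusion cascade, inverse normal transform, stepwise screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st
from scipy import stats

from famvar.phenotype_prep import (
    apply_exclusions,
    compute_uicr,
    inverse_normal_transform,
    screen_covariates,
)
from famvar.synthetic_data import SimulationScenario, simulate_dataset

from conftest import aligned


class TestUICR:
    def test_basic_ratio(self):
        assert compute_uicr(2.0, 1.0) == pytest.approx(200.0)
        assert compute_uicr(0.0, 5.0) == pytest.approx(0.0)

    def test_nonpositive_creatinine_is_missing(self):
        assert np.isnan(compute_uicr(1.5, 0.0))
        assert np.isnan(compute_uicr(1.5, np.nan))

    @given(
        st.floats(0.01, 1e4),
        st.floats(0.01, 1e4),
        st.floats(0.001, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    @seed(3)
    def test_scale_consistency(self, ui, ucr, factor):
        base = compute_uicr(ui, ucr)
        scaled = compute_uicr(ui * factor, ucr * factor)
        assert scaled == pytest.approx(base, rel=1e-9)


def _toy_table(rows):
    defaults = {
        "id": None,
        "family_id": None,
        "tsh": 2.0,
        "ft4": 1.2,
        "ui": 300.0,
        "ucr": 120.0,
        "age": 40.0,
        "bmi": 23.0,
        "tpoab": 5.0,
        "sex": "female",
        "overt_dysfunction": False,
        "prior_treatment": False,
        "pregnant": False,
        "thyroid_history": False,
        "family_history": False,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["id"] = f"I{i}"
        rec.update(row)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestExclusions:
    def test_toy_cascade_counts(self):
        table = _toy_table(
            [
                {"family_id": "A"},
                {"family_id": "A"},
                {"family_id": "A", "tpoab": 40.0},
                {"family_id": "B"},
                {"family_id": "B"},
                {"family_id": "C"},  # singleton family
            ]
        )
        out, tally = apply_exclusions(table, mode="main")
        assert len(out) == 4
        assert tally["tpoab_positive"] == 1
        assert tally["family_lt_2"] == 1
        assert sum(tally.values()) == len(table) - len(out)

    def test_euthyroid_excludes_out_of_range_tsh(self):
        table = _toy_table(
            [{"family_id": "A", "tsh": 7.0}, {"family_id": "A"}, {"family_id": "A"}]
        )
        out, tally = apply_exclusions(table, mode="euthyroid")
        assert tally["tsh_out_of_range"] == 1
        assert "I0" not in set(out["id"])

    def test_reference_boundaries_are_inclusive(self):
        table = _toy_table(
            [
                {"family_id": "A", "tsh": 0.62, "ft4": 0.89},
                {"family_id": "A", "tsh": 6.86, "ft4": 1.76},
            ]
        )
        out, tally = apply_exclusions(table, mode="euthyroid")
        assert len(out) == 2
        assert tally["tsh_out_of_range"] == 0 and tally["ft4_out_of_range"] == 0

    def test_tpoab_threshold_is_closed(self):
        table = _toy_table(
            [{"family_id": "A", "tpoab": 34.0}, {"family_id": "A"}, {"family_id": "A"}]
        )
        _, tally = apply_exclusions(table)
        assert tally["tpoab_positive"] == 1

    def test_missing_measurement_removed_not_zeroed(self):
        table = _toy_table(
            [{"family_id": "A", "ui": np.nan}, {"family_id": "A"}, {"family_id": "A"}]
        )
        out, tally = apply_exclusions(table)
        assert tally["missing_measurement"] == 1 and len(out) == 2

    @pytest.mark.parametrize("mode", ["main", "euthyroid"])
    def test_idempotent(self, mode):
        table = _toy_table(
            [
                {"family_id": "A", "tpoab": 50.0},
                {"family_id": "A", "tsh": 8.0},
                {"family_id": "A"},
                {"family_id": "A"},
                {"family_id": "B"},
                {"family_id": "B", "pregnant": True},
            ]
        )
        once, _ = apply_exclusions(table, mode=mode)
        twice, tally2 = apply_exclusions(once, mode=mode)
        assert len(twice) == len(once)
        assert all(v == 0 for v in tally2.values())

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            apply_exclusions(_toy_table([{"family_id": "A"}]), mode="bogus")


class TestInverseNormal:
    def test_symmetric_three_points(self):
        out = inverse_normal_transform([1.0, 2.0, 3.0])
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(-out[2])

    def test_blom_with_average_ranks(self):
        out = inverse_normal_transform([5.0, 5.0, 9.0])
        # tied pair gets average rank 1.5; Blom offset c = 3/8
        expected_tied = stats.norm.ppf((1.5 - 0.375) / (3 - 0.75 + 1))
        assert out[0] == pytest.approx(out[1])
        assert out[0] == pytest.approx(expected_tied)
        assert out[2] == pytest.approx(stats.norm.ppf((3 - 0.375) / 3.25))

    def test_missing_stays_missing(self):
        out = inverse_normal_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([np.nan, np.nan])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None)
    @seed(5)
    def test_monotone_in_input(self, values):
        out = inverse_normal_transform(values)
        order = np.argsort(np.asarray(values), kind="stable")
        diffs = np.diff(out[order])
        assert np.all(diffs >= -1e-12)

    def test_mean_zero_variance_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 3.0, size=500)  # skewed, tie-free
        out = inverse_normal_transform(x)
        assert abs(out.mean()) < 1e-8
        assert 0.9 <= out.var() <= 1.0


class TestScreenCovariates:
    @staticmethod
    def _dataset(seed, n_families=250):
        scenario = SimulationScenario(
            name="screen",
            n_families=n_families,
            model="univariate_ace",
            params={"h2": 0.5},
            covariate_effects={"age": 0.08, "sex": 0.08, "age2": 0.0},
            trait_transform="identity",
        )
        return simulate_dataset(scenario, seed)

    def test_true_effects_selected_null_excluded(self):
        selected_noise = 0
        reps = 20
        for rep in range(reps):
            ds = self._dataset(rep)
            rng = np.random.default_rng(1000 + rep)
            y = aligned(ds, "tsh")
            age = aligned(ds, "age")
            cand = pd.DataFrame(
                {
                    "age": age - 45.0,
                    "sex": ds.pedigree.sexes.astype(float),
                    "noise": rng.standard_normal(len(ds.pedigree)),
                }
            )
            model = screen_covariates(y, cand, ds.pedigree)
            assert "age" in model.selected and "sex" in model.selected
            if "noise" in model.selected:
                selected_noise += 1
        # nominal inclusion of a null covariate is p_enter = 0.10
        assert selected_noise / reps <= 0.30

    def test_empty_candidate_set(self):
        ds = self._dataset(0, n_families=40)
        y = aligned(ds, "tsh")
        model = screen_covariates(y, pd.DataFrame(index=range(len(ds.pedigree))), ds.pedigree)
        assert model.selected == []
        assert "intercept" in model.coefficients
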