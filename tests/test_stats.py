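"""Consistency summaries, the repeated-measures model, and the permutation test."""

import numpy as np
import pandas as pd
import pytest

from netsi import (
    CohortSpec,
    ConditionContrastModel,
    DegenerateScaleError,
    ROISet,
    SIMap,
    generate_cohort,
    global_consistency,
    minmax_scale,
    pairwise_difference,
    permutation_test,
    regional_consistency,
    subject_si_map,
)


class TestGlobalConsistency:
    def test_single_uniform_map(self):
        assert global_consistency([SIMap(np.full(10, 0.4), 0)]) == pytest.approx(0.4)

    def test_sum_then_mean(self):
        maps = [SIMap(np.full(8, 0.2), 0), SIMap(np.full(8, 0.3), 1)]
        assert global_consistency(maps) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self, rng):
        maps = [SIMap(rng.random(30), r) for r in range(7)]
        total = 0.0
        for v in range(30):
            for m in maps:
                total += m.values[v]
        assert global_consistency(maps) == pytest.approx(total / 30)

    def test_empty_map_set_rejected(self):
        with pytest.raises(ValueError):
            global_consistency([])


class TestMinMaxScale:
    def test_formula_on_three_values(self):
        scaled = minmax_scale({0: SIMap([0.2, 0.4, 0.6], 0)})
        assert np.allclose(scaled[0].values, [0.0, 0.5, 1.0])

    def test_already_spanning_unit_interval_unchanged(self):
        m = SIMap([0.0, 0.25, 1.0], 0)
        assert np.allclose(minmax_scale({0: m})[0].values, m.values)

    def test_joint_scaling_across_maps(self):
        scaled = minmax_scale({0: SIMap([0.2, 0.4], 0), 1: SIMap([0.6, 0.4], 1)})
        assert np.allclose(scaled[0].values, [0.0, 0.5])
        assert np.allclose(scaled[1].values, [1.0, 0.5])

    def test_order_preserved(self, rng):
        vals = rng.random(20)
        scaled = minmax_scale({0: SIMap(vals, 0)})[0].values
        assert np.array_equal(np.argsort(vals), np.argsort(scaled))

    def test_constant_maps_rejected(self):
        with pytest.raises(DegenerateScaleError):
            minmax_scale({0: SIMap(np.full(5, 0.3), 0), 1: SIMap(np.full(5, 0.3), 1)})


class TestRegionalConsistency:
    def test_uniform_map_returns_its_value(self):
        m = SIMap(np.full(10, 0.7), 0)
        assert regional_consistency(m, ROISet(0, [1, 3, 5])) == pytest.approx(0.7)

    def test_longhand_mean_on_toy_roi(self):
        m = SIMap([0.1, 0.2, 0.3, 0.4, 0.5, 0.9], 0)
        roi = ROISet(0, [0, 2, 3, 4, 5])
        assert regional_consistency(m, roi) == pytest.approx(
            (0.1 + 0.3 + 0.4 + 0.5 + 0.9) / 5
        )

    def test_full_universe_roi_is_whole_map_mean(self, rng):
        vals = rng.random(15)
        m = SIMap(vals, 0)
        assert regional_consistency(m, ROISet(0, np.arange(15))) == pytest.approx(
            vals.mean()
        )

    def test_scaled_regional_invariant_to_affine_input_shift(self, rng):
        # min-max then ROI mean is unchanged by a common affine rescale
        vals = {r: rng.random(20) * 0.5 for r in range(3)}
        roi = ROISet(1, [2, 5, 7, 11])
        maps_raw = {r: SIMap(v, r) for r, v in vals.items()}
        maps_affine = {r: SIMap(0.3 + 0.5 * v, r) for r, v in vals.items()}
        a = regional_consistency(minmax_scale(maps_raw)[1], roi)
        b = regional_consistency(minmax_scale(maps_affine)[1], roi)
        assert a == pytest.approx(b, abs=1e-12)


def _long_table(endog: np.ndarray, conditions, covariates: pd.DataFrame | None = None):
    rows = []
    for i in range(endog.shape[0]):
        for j, c in enumerate(conditions):
            row = {"subject_id": i, "condition": c, "value": endog[i, j]}
            rows.append(row)
    df = pd.DataFrame(rows)
    if covariates is not None:
        df = df.merge(covariates, on="subject_id")
    return df


class TestConditionContrastModel:
    conditions = ("Rest", "Easy", "Hard")

    def test_balanced_no_covariates_equals_raw_means(self, rng):
        y = rng.random((12, 3))
        model = ConditionContrastModel.from_dataframe(
            _long_table(y, self.conditions), covariates=(), conditions=self.conditions
        )
        res = model.fit()
        for j, c in enumerate(self.conditions):
            assert res.ls_means[c] == pytest.approx(y[:, j].mean())
        assert res.beta("Rest", "Easy") == pytest.approx(
            y[:, 0].mean() - y[:, 1].mean()
        )

    def test_beta_is_exact_difference_of_ls_means_and_antisymmetric(self, rng):
        y = rng.random((10, 3))
        cov = pd.DataFrame(
            {"subject_id": range(10), "age": rng.normal(76, 4, 10),
             "sex": rng.integers(0, 2, 10), "race": rng.integers(0, 2, 10)}
        )
        res = ConditionContrastModel.from_dataframe(
            _long_table(y, self.conditions, cov), conditions=self.conditions
        ).fit()
        for (a, b), c in res.pairwise.items():
            assert c.beta == res.ls_means[a] - res.ls_means[b]
            flipped = res.contrast(b, a)
            assert flipped.beta == -c.beta
            assert flipped.ci_low == -c.ci_high
            assert flipped.p_adjusted == c.p_adjusted

    def test_ls_means_invariant_to_row_order(self, rng):
        y = rng.random((8, 3))
        df = _long_table(y, self.conditions)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = ConditionContrastModel.from_dataframe(
            df, covariates=(), conditions=self.conditions
        ).fit()
        r2 = ConditionContrastModel.from_dataframe(
            shuffled, covariates=(), conditions=self.conditions
        ).fit()
        assert r1.ls_means == pytest.approx(r2.ls_means)

    def test_printed_style_contrast_arithmetic(self):
        ls = {"Rest": 0.4021, "Easy": 0.2202}
        assert pairwise_difference(ls, "Rest", "Easy") == pytest.approx(0.1819)

    def test_incomplete_subjects_dropped_and_counted(self, rng):
        y = rng.random((6, 3))
        df = _long_table(y, self.conditions)
        df = df[~((df.subject_id == 2) & (df.condition == "Hard"))]
        model = ConditionContrastModel.from_dataframe(
            df, covariates=(), conditions=self.conditions
        )
        assert model.n_dropped == 1
        assert model.endog.shape[0] == 5

    def test_too_few_subjects_rejected(self, rng):
        y = rng.random((2, 3))
        with pytest.raises(ValueError):
            ConditionContrastModel.from_dataframe(
                _long_table(y, self.conditions), covariates=(),
                conditions=self.conditions,
            )

    def test_recovers_planted_condition_effect_with_covariates(self, rng):
        # y_ij = mu_j + 0.02*age + 0.5*sex + corr. noise; n = 100 subjects
        n = 100
        age = rng.normal(76, 4, n)
        sex = rng.integers(0, 2, n)
        mu = np.array([0.5, 0.3, 0.25])
        cov = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.6], [0.5, 0.6, 1.0]]) * 0.04
        noise = rng.multivariate_normal(np.zeros(3), cov, size=n)
        y = mu + 0.02 * age[:, None] + 0.5 * sex[:, None] + noise
        covdf = pd.DataFrame({"subject_id": range(n), "age": age, "sex": sex})
        res = ConditionContrastModel.from_dataframe(
            _long_table(y, self.conditions, covdf),
            covariates=("age", "sex"),
            conditions=self.conditions,
        ).fit()
        c = res.pairwise[("Rest", "Easy")]
        assert c.ci_low <= mu[0] - mu[1] <= c.ci_high
        assert abs(c.beta - (mu[0] - mu[1])) < 0.05

    def test_summary_reports_ls_means_and_contrasts(self, rng):
        y = rng.random((8, 3))
        res = ConditionContrastModel.from_dataframe(
            _long_table(y, self.conditions), covariates=(),
            conditions=self.conditions,
        ).fit()
        text = res.summary()
        assert "Least-squares means" in text
        assert "Rest vs. Easy" in text
        assert "Bonferroni factor: 3" in text


class TestPermutationTest:
    def _maps(self, rng, n_subjects, n_nodes=40):
        return {
            s: SIMap(rng.random(n_nodes), 0) for s in range(n_subjects)
        }

    def test_identical_conditions_give_p_one(self, rng):
        maps = self._maps(rng, 10)
        roi = ROISet(0, np.arange(10))
        res = permutation_test(maps, dict(maps), roi, n_perm=200, seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_strong_planted_effect_detected(self):
        # jitter 0 vs 0.5 on the planted ROI: consistency collapses
        spec = CohortSpec(
            n_subjects=20,
            n_nodes=80,
            community_sizes=(20, 20, 20, 20),
            conditions=(("A", 0.0), ("B", 0.5)),
            n_timepoints=60,
            seed=8,
        )
        cohort = generate_cohort(spec)
        roi = ROISet(0, np.arange(20))
        maps_a = {
            s: subject_si_map(roi, cohort.ground_truth.planted[(s, "A")])
            for s in range(20)
        }
        maps_b = {
            s: subject_si_map(roi, cohort.ground_truth.planted[(s, "B")])
            for s in range(20)
        }
        res = permutation_test(maps_a, maps_b, roi, n_perm=1000, seed=1)
        assert res.p_value <= 0.01

    def test_null_p_values_approximately_uniform(self, rng):
        # Kolmogorov-Smirnov check over 200 independent null cohorts
        from scipy.stats import kstest

        pvals = []
        for rep in range(200):
            maps_a = self._maps(rng, 12, n_nodes=20)
            maps_b = self._maps(rng, 12, n_nodes=20)
            roi = ROISet(0, np.arange(20))
            pvals.append(
                permutation_test(maps_a, maps_b, roi, n_perm=200, seed=rep).p_value
            )
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_mismatched_subject_sets_rejected(self, rng):
        maps_a = self._maps(rng, 5)
        maps_b = self._maps(rng, 4)
        with pytest.raises(ValueError):
            permutation_test(maps_a, maps_b, ROISet(0, [0]), n_perm=200)

    def test_too_few_permutations_rejected(self, rng):
        maps = self._maps(rng, 5)
        with pytest.raises(ValueError):
            permutation_test(maps, maps, ROISet(0, [0]), n_perm=50)
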