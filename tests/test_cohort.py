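"""Synthetic cohort generator: correlation targets, jitter, determinism."""

import numpy as np
import pytest

from netsi import (
    CohortSpec,
    generate_block_timeseries,
    generate_cohort,
    generate_covariates,
    generate_vas_responses,
    template_partition,
)


def _within_block_mean_r(ts: np.ndarray, labels: np.ndarray) -> float:
    c = np.corrcoef(ts)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(labels.size, dtype=bool)
    return float(c[same & off].mean())


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"noise_sd": 0.0},
            {"noise_sd": -1.0},
            {"community_sizes": (30, 30)},  # does not sum to n_nodes
            {"community_sizes": (80, 0)},  # empty community
            {"conditions": (("Rest", -0.1),)},
            {"conditions": (("Rest", 1.5),)},
            {"within_r": 1.0},
            {"between_r": 0.7},  # >= within_r
            {"n_timepoints": 10},
            {"n_subjects": 0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        base = dict(
            n_subjects=3, n_nodes=80, community_sizes=(40, 40), n_timepoints=100
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            CohortSpec(**base)


class TestBlockTimeseries:
    def test_pure_noise_has_no_correlation_structure(self):
        # within_r = 0, one community: nodes are independent noise
        spec = CohortSpec(
            n_subjects=1,
            n_nodes=40,
            community_sizes=(40,),
            within_r=0.0,
            between_r=0.0,
            n_timepoints=4000,
            seed=5,
        )
        ts = generate_block_timeseries(spec, template_partition((40,)))
        c = np.corrcoef(ts)
        off = c[~np.eye(40, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_within_block_correlation_hits_target(self):
        # loading solves r = lambda^2 / (lambda^2 + sigma^2); Monte-Carlo check
        spec = CohortSpec(
            n_subjects=1,
            n_nodes=40,
            community_sizes=(20, 20),
            within_r=0.6,
            between_r=0.0,
            n_timepoints=2000,
            seed=7,
        )
        labels = template_partition((20, 20)).labels
        ts = generate_block_timeseries(spec, labels)
        assert _within_block_mean_r(ts, labels) == pytest.approx(0.6, abs=0.05)

    def test_correlations_converge_with_long_series(self):
        # law of large numbers at T = 5000, within and between targets
        spec = CohortSpec(
            n_subjects=1,
            n_nodes=60,
            community_sizes=(30, 30),
            within_r=0.5,
            between_r=0.15,
            n_timepoints=5000,
            seed=9,
        )
        labels = template_partition((30, 30)).labels
        c = np.corrcoef(generate_block_timeseries(spec, labels))
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(60, dtype=bool)
        assert c[same & off].mean() == pytest.approx(0.5, abs=0.03)
        assert c[~same].mean() == pytest.approx(0.15, abs=0.03)

    def test_identical_seed_bit_identical(self):
        spec = CohortSpec(
            n_subjects=1, n_nodes=40, community_sizes=(20, 20), n_timepoints=100, seed=3
        )
        part = template_partition((20, 20))
        a = generate_block_timeseries(spec, part)
        b = generate_block_timeseries(spec, part)
        assert np.array_equal(a, b)

    def test_empty_partition_rejected(self):
        spec = CohortSpec(
            n_subjects=1, n_nodes=40, community_sizes=(20, 20), n_timepoints=100
        )
        with pytest.raises(ValueError):
            generate_block_timeseries(spec, np.empty(0, dtype=int))


class TestCohortJitter:
    def _spec(self, conditions, seed=21, n_subjects=8):
        return CohortSpec(
            n_subjects=n_subjects,
            n_nodes=80,
            community_sizes=(20, 20, 20, 20),
            conditions=conditions,
            n_timepoints=60,
            seed=seed,
        )

    def test_zero_jitter_keeps_template_everywhere(self):
        cohort = generate_cohort(self._spec((("Rest", 0.0),)))
        template = cohort.ground_truth.template
        for key, part in cohort.ground_truth.planted.items():
            assert part == template
            assert cohort.ground_truth.jittered_nodes[key].size == 0

    def test_full_jitter_gives_analytic_chance_agreement(self):
        # jitter = 1 with k = 4 equal communities: every node moves to a
        # uniformly random other community, so a pair formerly together
        # stays together w.p. 1/(k-1) = 1/3, and a formerly split pair
        # reunites w.p. 2/(k-1)^2 = 2/9 (shifts s, t uniform on {1,2,3}
        # with s - t = d mod 4 for fixed d != 0)
        cohort = generate_cohort(self._spec((("Hard", 1.0),), n_subjects=12))
        template = cohort.ground_truth.template.labels
        same_before = template[:, None] == template[None, :]
        off = ~np.eye(template.size, dtype=bool)
        stay, reunite = [], []
        for p in cohort.ground_truth.planted.values():
            same_after = p.labels[:, None] == p.labels[None, :]
            stay.append(same_after[same_before & off].mean())
            reunite.append(same_after[~same_before].mean())
        assert float(np.mean(stay)) == pytest.approx(1 / 3, abs=0.03)
        assert float(np.mean(reunite)) == pytest.approx(2 / 9, abs=0.03)

    def test_jitter_fraction_controls_moved_node_count(self):
        cohort = generate_cohort(self._spec((("Easy", 0.25),)))
        for key, moved in cohort.ground_truth.jittered_nodes.items():
            assert moved.size == 20  # 0.25 * 80
            assert np.all(
                cohort.ground_truth.planted[key].labels[moved]
                != cohort.ground_truth.template.labels[moved]
            ) or moved.size == 0

    def test_cohort_deterministic_under_seed(self):
        spec = self._spec((("Rest", 0.0), ("Hard", 0.5)), seed=4, n_subjects=3)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for key in a.timeseries:
            assert np.array_equal(a.timeseries[key], b.timeseries[key])
            assert a.ground_truth.planted[key] == b.ground_truth.planted[key]


class TestVASGenerator:
    def test_scores_are_bounded_integers(self):
        df = generate_vas_responses(300, location_shift=30.0, seed=1)
        for col in ("easy_score", "hard_score"):
            assert df[col].between(0, 100).all()
            assert df[col].dtype.kind == "i"

    def test_no_shift_is_symmetric(self):
        df = generate_vas_responses(4000, location_shift=0.0, seed=2)
        frac_pos = (df.easy_score > df.hard_score).mean()
        frac_neg = (df.easy_score < df.hard_score).mean()
        assert frac_pos == pytest.approx(frac_neg, abs=0.04)

    def test_positive_shift_gives_majority_easy_over_hard(self):
        df = generate_vas_responses(200, location_shift=20.0, seed=3)
        assert (df.easy_score > df.hard_score).sum() > 100

    def test_reproducible_under_seed(self):
        a = generate_vas_responses(50, 5.0, seed=9)
        b = generate_vas_responses(50, 5.0, seed=9)
        assert a.equals(b)


def test_covariates_emulate_cohort_demographics():
    df = generate_covariates(2000, seed=6)
    assert df.age.mean() == pytest.approx(76.1, abs=0.5)
    assert df.sex.mean() == pytest.approx(0.554, abs=0.05)
    assert df.race.mean() == pytest.approx(0.083, abs=0.03)
    assert generate_covariates(20, seed=1).equals(generate_covariates(20, seed=1))
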