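"""The five sampling strategies: determinism, quota and shortfall rules,
weight proportionality, and bootstrap coverage."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mdsieve as m


def _uniform_series(n, seed=0):
    return m.generate_property_series("uniform", {"a": 0.0, "b": 1.0}, n, seed)


SAMPLER_CALLS = {
    "random": lambda seed: m.sample_random(100, 10, seed),
    "uniform": lambda seed: m.sample_uniform(_uniform_series(100), 10, 5, seed),
    "stratified": lambda seed: m.sample_stratified(
        m.StrataAssignment(np.repeat(["A", "B"], 50)), 10, seed),
    "weighted": lambda seed: m.sample_weighted(
        m.FrameWeights(np.linspace(1, 2, 100)), 10, seed),
    "bootstrap": lambda seed: m.sample_bootstrap(100, 10, 3, seed),
}


@pytest.mark.parametrize("name", sorted(SAMPLER_CALLS))
def test_samplers_deterministic_under_fixed_seed(name):
    call = SAMPLER_CALLS[name]
    first, second = call(123), call(123)
    if name == "bootstrap":
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a.frame_indices, b.frame_indices)
    else:
        np.testing.assert_array_equal(first.frame_indices, second.frame_indices)


@pytest.mark.parametrize("name", ["random", "uniform", "stratified", "weighted"])
def test_without_replacement_samples_have_no_duplicates(name):
    sample = SAMPLER_CALLS[name](7)
    assert len(np.unique(sample.frame_indices)) == len(sample)
    assert not sample.replacement


class TestRandom:
    def test_full_size_exhausts_all_frames(self):
        sample = m.sample_random(10, 10, seed=0)
        np.testing.assert_array_equal(sample.frame_indices, np.arange(10))

    def test_oversized_request_rejected(self):
        with pytest.raises(m.SampleSizeError):
            m.sample_random(10, 11, seed=0)

    def test_inclusion_frequencies_uniform(self):
        # per-frame inclusion ~ Binomial(n_seeds, size/n_frames); the max
        # over 40 frames is checked at 4 sigma (union-bound safe)
        n_frames, size, n_seeds = 40, 10, 1000
        hits = np.zeros(n_frames)
        for seed in range(n_seeds):
            hits[m.sample_random(n_frames, size, seed).frame_indices] += 1
        p = size / n_frames
        sigma = np.sqrt(p * (1 - p) / n_seeds)
        assert np.max(np.abs(hits / n_seeds - p)) < 4 * sigma


class TestUniform:
    def test_equal_quotas_when_strata_suffice(self):
        series = _uniform_series(1000)
        sample = m.sample_uniform(series, 20, 4, seed=1)
        assert len(sample) == 20
        assert sample.shortfall == 0
        edges = np.linspace(series.values.min(), series.values.max(), 5)
        occupancy = np.histogram(series.values[sample.frame_indices], edges)[0]
        np.testing.assert_array_equal(occupancy, [5, 5, 5, 5])

    def test_deficient_stratum_reports_shortfall(self):
        # 2 frames near 1.0, plenty near 0.0: upper stratum cannot fill
        values = np.concatenate([np.linspace(0, 0.4, 98), [1.0, 0.99]])
        series = m.PropertySeries(values, "toy")
        sample = m.sample_uniform(series, 10, 2, seed=2)
        assert sample.shortfall == 3
        assert len(sample) == 7
        assert {98, 99} <= set(sample.frame_indices.tolist())

    def test_skewed_series_flattened(self):
        # 900 frames in the low mode, 100 in the high: sample occupancy per
        # stratum is within +-1 of quota wherever the stratum suffices
        rng = np.random.default_rng(3)
        values = np.concatenate([
            rng.uniform(0.0, 0.5, 900), rng.uniform(0.5, 1.0, 100)
        ])
        series = m.PropertySeries(values, "toy")
        sample = m.sample_uniform(series, 40, 4, seed=3)
        assert sample.shortfall == 0
        edges = np.linspace(values.min(), values.max(), 5)
        occupancy = np.histogram(values[sample.frame_indices], edges)[0]
        assert np.all(np.abs(occupancy - 10) <= 1)

    def test_constant_series_rejected(self):
        series = m.PropertySeries(np.full(50, 2.0), "toy")
        with pytest.raises(m.DegenerateRangeError):
            m.sample_uniform(series, 10, 2, seed=0)

    def test_remainder_goes_to_lowest_occupied_strata(self):
        series = _uniform_series(1000)
        sample = m.sample_uniform(series, 11, 3, seed=4)
        edges = np.linspace(series.values.min(), series.values.max(), 4)
        occupancy = np.histogram(series.values[sample.frame_indices], edges)[0]
        np.testing.assert_array_equal(occupancy, [4, 4, 3])


class TestStratified:
    def test_equal_quota_per_replica(self):
        strata = m.StrataAssignment(np.repeat(["A", "B", "C"], 100))
        sample = m.sample_stratified(strata, 30, seed=5)
        labels = strata.labels[sample.frame_indices]
        assert {lab: int(n) for lab, n in
                zip(*np.unique(labels, return_counts=True))} == {
                    "A": 10, "B": 10, "C": 10}

    def test_deficiency_rule(self):
        strata = m.StrataAssignment(np.array(["A"] * 100 + ["B"] * 3))
        sample = m.sample_stratified(strata, 20, seed=6)
        labels = strata.labels[sample.frame_indices]
        assert int(np.sum(labels == "A")) == 10
        assert int(np.sum(labels == "B")) == 3
        assert sample.shortfall == 7

    def test_single_label_equals_random_on_those_frames(self):
        strata = m.StrataAssignment(np.array(["X"] * 80))
        for seed in (0, 1, 17):
            a = m.sample_stratified(strata, 12, seed=seed)
            b = m.sample_random(80, 12, seed=seed)
            np.testing.assert_array_equal(a.frame_indices, b.frame_indices)

    def test_size_below_label_count_rejected(self):
        strata = m.StrataAssignment(np.array(["A", "B", "C"]))
        with pytest.raises(m.SampleSizeError):
            m.sample_stratified(strata, 2, seed=0)


class TestWeighted:
    def test_degenerate_mass_always_selects_it(self):
        weights = m.FrameWeights(np.array([1.0, 0.0, 0.0, 0.0]))
        for seed in range(20):
            sample = m.sample_weighted(weights, 1, seed)
            assert sample.frame_indices.tolist() == [0]

    def test_zero_weight_frames_never_selected(self):
        w = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        for seed in range(30):
            sample = m.sample_weighted(m.FrameWeights(w), 3, seed)
            assert not {1, 3} & set(sample.frame_indices.tolist())

    def test_ninety_ten_binomial_recovery(self):
        # single draw from weights (0.9, 0.1): frame 0 selected ~90% of
        # runs, within 3 sigma over 1000 seeds
        weights = m.FrameWeights(np.array([0.9, 0.1]))
        hits = sum(m.sample_weighted(weights, 1, seed).frame_indices[0] == 0
                   for seed in range(1000))
        sigma = np.sqrt(0.9 * 0.1 / 1000)
        assert abs(hits / 1000 - 0.9) < 3 * sigma

    def test_equal_weights_match_random_inclusion(self):
        # distributional equivalence with sample_random: per-frame
        # inclusion frequencies agree within 4 sigma over 500 seeds
        n_frames, size, n_seeds = 30, 6, 500
        weights = m.FrameWeights(np.full(n_frames, 1.0))
        hits_w = np.zeros(n_frames)
        hits_r = np.zeros(n_frames)
        for seed in range(n_seeds):
            hits_w[m.sample_weighted(weights, size, seed).frame_indices] += 1
            hits_r[m.sample_random(n_frames, size, seed).frame_indices] += 1
        p = size / n_frames
        sigma = np.sqrt(2 * p * (1 - p) / n_seeds)   # difference of two rates
        assert np.max(np.abs(hits_w - hits_r) / n_seeds) < 4 * sigma

    def test_invalid_weights_rejected(self):
        with pytest.raises(m.InputError):
            m.FrameWeights(np.zeros(5))
        with pytest.raises(m.InputError):
            m.FrameWeights(np.array([1.0, -0.1]))

    def test_without_replacement_capped_by_positive_weights(self):
        weights = m.FrameWeights(np.array([1.0, 1.0, 0.0]))
        with pytest.raises(m.SampleSizeError):
            m.sample_weighted(weights, 3, seed=0)
        sample = m.sample_weighted(weights, 3, seed=0, replacement=True)
        assert len(sample) == 3


class TestWeightsFromFrequency:
    def test_uniform_occupancy_gives_equal_weights(self):
        values = np.tile([0.1, 0.9], 50)  # exactly 50/50 over 2 bins
        series = m.PropertySeries(values, "toy")
        weights = m.weights_from_frequency(series, n_bins=2)
        np.testing.assert_allclose(weights.normalized(), np.full(100, 0.01))

    def test_ninety_ten_bins_weight_ratio_is_nine(self):
        values = np.concatenate([np.full(90, 0.1), np.full(10, 0.9)])
        series = m.PropertySeries(values, "toy")
        weights = m.weights_from_frequency(series, n_bins=2)
        w = weights.normalized()
        assert w[0] / w[-1] == pytest.approx(9.0)
        # per the stated rule: bin-mass 0.9 vs 0.1 per frame, then
        # normalized over frames: 0.9/82 and 0.1/82
        assert w[0] == pytest.approx(0.9 / 82.0)
        assert w[-1] == pytest.approx(0.1 / 82.0)

    def test_range_override_zeroes_outside_frames(self):
        values = np.concatenate([np.full(50, 0.5), np.full(50, 10.0)])
        series = m.PropertySeries(values, "toy")
        weights = m.weights_from_frequency(series, n_bins=4,
                                           range_override=(0.0, 1.0))
        w = weights.normalized()
        np.testing.assert_allclose(w[:50], np.full(50, 0.02))
        np.testing.assert_allclose(w[50:], 0.0)


class TestBootstrap:
    def test_distinct_fraction_matches_closed_form(self):
        # E[distinct/N] = 1 - (1 - 1/N)^m; Monte-Carlo mean over 500
        # replicates within 3 standard errors of the estimate
        n = size = 100
        replicates = m.sample_bootstrap(n, size, 500, seed=9)
        fractions = np.array([
            len(np.unique(r.frame_indices)) / n for r in replicates
        ])
        expected = 1.0 - (1.0 - 1.0 / n) ** size
        se = fractions.std(ddof=1) / np.sqrt(len(fractions))
        assert abs(fractions.mean() - expected) < 3 * se

    def test_replicates_differ(self):
        replicates = m.sample_bootstrap(100, 20, 5, seed=10)
        assert len({tuple(r.frame_indices) for r in replicates}) > 1

    def test_replicate_reproducible_from_seed_and_index(self):
        full = m.sample_bootstrap(100, 20, 5, seed=11)
        # regenerating a longer run reproduces the earlier replicates
        longer = m.sample_bootstrap(100, 20, 8, seed=11)
        for a, b in zip(full, longer):
            np.testing.assert_array_equal(a.frame_indices, b.frame_indices)

    def test_size_one(self):
        for r in m.sample_bootstrap(50, 1, 4, seed=12):
            assert len(r) == 1
            assert r.replacement


@given(seed=st.integers(min_value=0, max_value=2**31 - 1),
       size=st.integers(min_value=1, max_value=50))
def test_random_sampler_pure_in_seed_and_size(seed, size):
    a = m.sample_random(50, size, seed)
    b = m.sample_random(50, size, seed)
    np.testing.assert_array_equal(a.frame_indices, b.frame_indices)
    assert len(np.unique(a.frame_indices)) == size
    assert a.frame_indices.min() >= 0 and a.frame_indices.max() < 50
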