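"""Peri-event analysis: baselines, rank-sum battery, auROC, response vector."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalmod import responses, synth


def _pairwise_auroc(sample, baseline):
    """Independent oracle: exhaustive pair enumeration."""
    wins = ties = 0
    for x in sample:
        for y in baseline:
            wins += x > y
            ties += x == y
    return (wins + 0.5 * ties) / (len(sample) * len(baseline))


def _enumeration_rank_sum_p(x, y):
    """Independent oracle: two-sided p by exhaustive split enumeration of
    the Mann-Whitney U statistic (value comparisons, no rank machinery)."""
    pooled = list(x) + list(y)
    n, n1 = len(pooled), len(x)

    def u_stat(idx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(n) if i not in idx]
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in a for yi in b)

    obs_dev = abs(u_stat(set(range(n1))) - n1 * (n - n1) / 2)
    hits = sum(
        1 for c in combinations(range(n), n1)
        if abs(u_stat(set(c)) - n1 * (n - n1) / 2) >= obs_dev - 1e-12
    )
    return hits / comb(n, n1)


class TestBaseline:
    def test_no_spikes_gives_zeros(self):
        rates = responses.baseline_rates([], [5.0, 10.0])
        assert np.array_equal(rates, [0.0, 0.0])

    def test_single_spike_in_window_rate_two(self):
        rates = responses.baseline_rates([4.25], [5.0])
        assert rates[0] == 2.0  # 1 spike / 0.5 s

    def test_homogeneous_rate_recovered(self, rng):
        spikes = np.sort(rng.uniform(0, 1000, 10_000))  # 10 spikes/s
        onsets = np.linspace(5, 995, 100)
        rates = responses.baseline_rates(spikes, onsets)
        assert abs(rates.mean() - 10.0) <= 1.0

    def test_window_outside_baseline_not_counted(self):
        rates = responses.baseline_rates([4.51, 3.99], [5.0])
        assert rates[0] == 0.0


class TestRankSum:
    def test_separated_samples_exact_enumeration(self):
        # all C(10,5)=252 splits; two extreme orderings -> p = 2/252
        p = responses.rank_sum_p([0, 0, 0, 0, 0], [8, 10, 12, 9, 11])
        assert p == pytest.approx(0.0079, abs=0.0001)
        adj = min(4 * p, 1.0)
        assert adj == pytest.approx(0.0317, abs=0.001)

    def test_matches_enumeration_oracle_small_samples(self, rng):
        for _ in range(10):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.integers(0, 6, n1).astype(float)
            y = rng.integers(0, 6, n2).astype(float)
            assert responses.rank_sum_p(x, y) == pytest.approx(
                _enumeration_rank_sum_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_boundary(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        exact = responses.rank_sum_p(x, y, exact_max_n=8)
        approx = responses.rank_sum_p(x, y, exact_max_n=0)
        assert approx == pytest.approx(exact, abs=0.02)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            responses.rank_sum_p([1.0], [2.0, 3.0])


class TestResponsiveness:
    def test_identical_samples_give_p_one(self, rng):
        x = rng.poisson(3, 40).astype(float)
        assert responses.rank_sum_p(x, x) == pytest.approx(1.0, abs=0.01)

    def test_unmodulated_poisson_unit_not_responsive(self, rng):
        spikes = np.sort(rng.uniform(0, 200, 1000))  # 5 Hz, no modulation
        firsts = np.linspace(5, 95, 10)
        subs = np.linspace(105, 195, 20)
        res = responses.responsiveness_test(spikes, firsts, subs)
        assert res.testable
        assert not res.responsive

    def test_planted_excitation_detected(self, long_usv_stream, profiles):
        flagged = 0
        for s in range(20):
            spikes = synth.gen_spike_train(
                profiles["E1"], long_usv_stream, 1000.0, seed=700 + s)
            res = responses.responsiveness_test(
                spikes, long_usv_stream.first_onsets,
                long_usv_stream.subsequent_onsets)
            flagged += res.responsive
        assert flagged >= 19

    def test_untestable_with_single_trial(self):
        res = responses.responsiveness_test(np.arange(100.0), [5.0], [6.0, 7.0])
        assert not res.testable and not res.responsive


class TestAuroc:
    def test_frozen_pairwise_example(self):
        assert responses.auroc([2, 4], [1, 3]) == 0.75

    def test_identical_distributions_half(self, rng):
        x = rng.normal(0, 1, 50)
        assert responses.auroc(x, x) == pytest.approx(0.5)

    def test_complete_separation_one(self):
        assert responses.auroc([5, 6, 7], [1, 2, 3]) == 1.0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 11, size=2)
            x = rng.integers(0, 5, n1).astype(float)
            y = rng.integers(0, 5, n2).astype(float)
            assert responses.auroc(x, y) == pytest.approx(
                _pairwise_auroc(x, y), abs=1e-12)

    def test_antisymmetry(self, rng):
        x = rng.poisson(3, 30).astype(float)
        y = rng.poisson(5, 25).astype(float)
        assert responses.auroc(x, y) + responses.auroc(y, x) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(0, 20), min_size=2, max_size=12),
           st.lists(st.integers(0, 20), min_size=2, max_size=12))
    def test_monotone_transform_invariance(self, xs, ys):
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        direct = responses.auroc(x, y)
        transformed = responses.auroc(np.exp(x / 5), np.exp(y / 5))
        assert direct == pytest.approx(transformed, abs=1e-12)

    def test_empty_baseline_raises(self):
        with pytest.raises(ValueError):
            responses.auroc([1.0], [])


class TestResponseVector:
    def test_flat_input_gives_all_half(self):
        vec = responses.response_vector(np.full(40, 0.5), np.full(40, 0.5))
        assert vec.shape == (25,)
        assert np.all(vec == 0.5)

    def test_window_selection(self):
        first = np.arange(40, dtype=float)
        sub = 100 + np.arange(40, dtype=float)
        vec = responses.response_vector(first, sub)
        assert np.array_equal(vec[:15], np.arange(10, 25))
        assert np.array_equal(vec[15:], 100 + np.arange(15, 25))

    def test_wrong_grid_raises(self):
        with pytest.raises(ValueError):
            responses.response_vector(np.full(39, 0.5), np.full(40, 0.5))

    def test_planted_excitation_raises_post_onset_entries(
            self, long_usv_stream, profiles):
        spikes = synth.gen_spike_train(profiles["E1"], long_usv_stream, 1000.0, seed=9)
        prof = responses.analyze_unit(
            "e1", spikes, long_usv_stream.first_onsets,
            long_usv_stream.subsequent_onsets)
        assert prof.vector25[10:15].mean() > 0.5


class TestPeriEventMatrix:
    def test_shapes_and_rate_identity(self, rng):
        spikes = np.sort(rng.uniform(0, 100, 2000))
        onsets = np.linspace(5, 95, 30)
        peri = responses.peri_event_matrix(spikes, onsets)
        assert peri.counts.shape == (30, 40)
        assert np.allclose(peri.rates, peri.counts / 0.05)

    def test_smoothing_preserves_mean_in_interior(self):
        counts = np.zeros((1, 40))
        counts[0, 20] = 1.0
        peri = responses.PeriEventMatrix(
            "first", counts, counts / 0.05,
            responses._moving_average(counts / 0.05))
        assert peri.smoothed[0, 18:23].sum() == pytest.approx(20.0)
        assert peri.smoothed[0, 20] == pytest.approx(4.0)  # 20/5 bins


class TestCallDiscrimination:
    def test_identical_rates_not_discriminating(self):
        spikes = np.arange(0, 100, 0.1)
        p, flag = responses.call_discrimination_test(
            spikes, np.linspace(5, 45, 10), np.linspace(55, 95, 10))
        assert not flag and p > 0.5

    def test_strong_rate_difference_detected(self, rng):
        flat_on = np.linspace(5, 95, 10)
        fm_on = np.linspace(105, 195, 10)
        slow = rng.uniform(0, 100, 200)  # 2 spikes/s
        fast = rng.uniform(100, 200, 2000)  # 20 spikes/s
        spikes = np.sort(np.concatenate([slow, fast]))
        p, flag = responses.call_discrimination_test(spikes, flat_on, fm_on)
        assert flag and p < 0.001

    def test_missing_call_type_untestable(self):
        p, flag = responses.call_discrimination_test(np.arange(10.0), [5.0], [1.0, 2.0])
        assert not flag and np.isnan(p)
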