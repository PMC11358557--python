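"""Amplitude distributions, Tsallis/Shannon entropy, and the sliding engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tseeg as T
from tseeg.entropy import EntropyConfig, max_tsallis_entropy
from conftest import random_distribution


def uniform_dist(n):
    return T.ProbabilityDistribution(
        probabilities=np.full(n, 1.0 / n), bin_edges=np.arange(n + 1, dtype=float)
    )


class TestAmplitudeDistribution:
    def test_constant_window_degenerates_to_one_bin(self):
        d = T.amplitude_distribution(np.array([5.0, 5.0, 5.0, 5.0]), 4)
        np.testing.assert_array_equal(d.probabilities, [1.0])

    def test_two_level_window(self):
        d = T.amplitude_distribution(np.array([0.0, 0.0, 1.0, 1.0]), 2)
        np.testing.assert_allclose(d.probabilities, [0.5, 0.5])

    def test_ramp_fills_bins_evenly(self):
        d = T.amplitude_distribution(np.arange(8.0), 4)
        np.testing.assert_allclose(d.probabilities, [0.25, 0.25, 0.25, 0.25])

    def test_matches_numpy_histogram(self, rng):
        for _ in range(50):
            x = rng.standard_normal(rng.integers(10, 400))
            bins = int(rng.integers(1, 30))
            d = T.amplitude_distribution(x, bins)
            counts, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
            np.testing.assert_array_equal(
                np.round(d.probabilities * x.size).astype(int), counts
            )

    def test_sqrt_rule(self):
        d = T.amplitude_distribution(np.arange(200.0), "sqrt")
        assert d.n_bins == 15  # ceil(sqrt(200))

    def test_probabilities_sum_to_one(self, rng):
        d = T.amplitude_distribution(rng.standard_normal(333), 17)
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            T.amplitude_distribution(np.array([1.0, np.nan, 2.0]), 2)


class TestEntropyValues:
    def test_certainty_has_zero_entropy(self):
        d = T.ProbabilityDistribution(np.array([1.0]), np.array([0.0, 1.0]))
        for q in (0.5, 2, 3, 4):
            assert T.tsallis_entropy(d, q) == 0.0
        assert T.shannon_entropy(d) == 0.0

    @pytest.mark.parametrize("q", [2, 3, 4])
    @pytest.mark.parametrize("n", [2, 4, 8, 16])
    def test_uniform_closed_form(self, q, n):
        expected = (1.0 - n ** (1.0 - q)) / (q - 1.0)
        assert T.tsallis_entropy(uniform_dist(n), q) == pytest.approx(expected, abs=1e-15)

    def test_uniform_examples(self):
        assert T.tsallis_entropy(uniform_dist(4), 3) == pytest.approx(0.46875)
        assert T.tsallis_entropy(uniform_dist(2), 2) == pytest.approx(0.5)

    def test_shannon_uniform_and_hand_case(self):
        assert T.shannon_entropy(uniform_dist(4)) == pytest.approx(math.log(4))
        d = T.ProbabilityDistribution(np.array([0.5, 0.25, 0.25]), np.arange(4.0))
        assert T.shannon_entropy(d) == pytest.approx(1.0397, abs=1e-4)

    def test_q_one_directed_to_shannon(self):
        with pytest.raises(ValueError, match="[Ss]hannon"):
            T.tsallis_entropy(uniform_dist(2), 1)
        with pytest.raises(ValueError):
            T.tsallis_entropy(uniform_dist(2), -2)

    def test_q_to_one_limit_approaches_shannon(self, rng):
        for _ in range(200):
            d = random_distribution(rng, int(rng.integers(2, 40)))
            sh = T.shannon_entropy(d)
            for q in (1 - 1e-4, 1 + 1e-4):
                assert abs(T.tsallis_entropy(d, q) - sh) < 1e-3

    def test_pseudo_additivity(self, rng):
        for _ in range(200):
            dx = random_distribution(rng, int(rng.integers(2, 12)))
            dy = random_distribution(rng, int(rng.integers(2, 12)))
            joint = T.ProbabilityDistribution(
                np.outer(dx.probabilities, dy.probabilities).ravel(),
                np.arange(dx.n_bins * dy.n_bins + 1, dtype=float),
            )
            for q in (0.5, 2.0, 3.0, 4.0):
                ex, ey = T.tsallis_entropy(dx, q), T.tsallis_entropy(dy, q)
                exy = T.tsallis_entropy(joint, q)
                assert exy == pytest.approx(ex + ey + (1 - q) * ex * ey, abs=1e-10)
                if q > 1 and ex > 0 and ey > 0:
                    assert exy < ex + ey  # subextensive regime

    @given(
        ps=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=30),
        q=st.sampled_from([0.5, 2.0, 3.0, 4.0]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_uniform_maximum(self, ps, q):
        p = np.array(ps) / sum(ps)
        p[-1] += 1.0 - p.sum()
        d = T.ProbabilityDistribution(p, np.arange(p.size + 1, dtype=float))
        e = T.tsallis_entropy(d, q)
        bound = max_tsallis_entropy(p.size, q)
        assert -1e-12 <= e <= bound + 1e-12
        assert T.tsallis_entropy(uniform_dist(p.size), q) == pytest.approx(bound)


def naive_sliding(sig, config):
    """Independent oracle: recompute every window from scratch."""
    w, delta = config.window_w, config.step_delta
    values, starts = [], []
    s = 0
    while s + w <= sig.size:
        d = T.amplitude_distribution(sig[s : s + w], config.n_bins)
        if config.q == 1:
            values.append(T.shannon_entropy(d))
        else:
            values.append(T.tsallis_entropy(d, config.q))
        starts.append(s)
        s += delta
    return np.array(values), np.array(starts)


class TestSlidingEntropy:
    def test_window_enumeration(self):
        cfg = EntropyConfig(q=3, window_w=4, step_delta=2, n_bins=2)
        s = T.sliding_entropy(np.arange(12.0), cfg)
        np.testing.assert_array_equal(s.starts, [0, 2, 4, 6, 8])

    def test_constant_signal_all_zero(self):
        cfg = EntropyConfig(q=2, window_w=10, step_delta=5, n_bins=4)
        s = T.sliding_entropy(np.full(100, 3.3), cfg)
        np.testing.assert_array_equal(s.values, 0.0)

    def test_single_window_reduces_to_whole_signal_entropy(self, rng):
        x = rng.standard_normal(64)
        cfg = EntropyConfig(q=3, window_w=64, step_delta=64, n_bins=8)
        s = T.sliding_entropy(x, cfg)
        assert len(s) == 1
        assert s.values[0] == T.tsallis_entropy(T.amplitude_distribution(x, 8), 3)

    @pytest.mark.parametrize("q", [1.0, 2.0, 3.0])
    def test_matches_naive_oracle_exactly(self, q, rng):
        for _ in range(20):
            n = int(rng.integers(50, 2000))
            w = int(rng.integers(4, min(n, 300)))
            cfg = EntropyConfig(
                q=q, window_w=w, step_delta=int(rng.integers(1, w + 1)),
                n_bins=int(rng.integers(2, 25)),
            )
            x = rng.standard_normal(n)
            got = T.sliding_entropy(x, cfg)
            exp_vals, exp_starts = naive_sliding(x, cfg)
            assert len(got) == (n - w) // cfg.step_delta + 1
            np.testing.assert_array_equal(got.starts, exp_starts)
            np.testing.assert_array_equal(got.values, exp_vals)

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            T.sliding_entropy(np.arange(5.0), EntropyConfig(window_w=10, step_delta=5))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EntropyConfig(window_w=1)
        with pytest.raises(ValueError):
            EntropyConfig(window_w=10, step_delta=11)
        with pytest.raises(ValueError):
            EntropyConfig(q=-1)


class TestEntropyFeatures:
    def test_hand_cases(self):
        cfg = EntropyConfig(window_w=2, step_delta=1, n_bins=2)
        mk = lambda vals: T.EntropySeries(np.array(vals), np.arange(len(vals)), cfg)
        assert T.entropy_features(mk([0.0, 0.0, 0.0])) == T.EntropyFeatures(0.0, 0.0)
        assert T.entropy_features(mk([0.5])) == T.EntropyFeatures(0.5, 0.0)
        f = T.entropy_features(mk([0.2, 0.4, 0.6]))
        assert f.mean == pytest.approx(0.4) and f.variance == pytest.approx(0.04)

    def test_empty_series_rejected(self):
        cfg = EntropyConfig(window_w=2, step_delta=1)
        with pytest.raises(ValueError, match="empty"):
            T.entropy_features(T.EntropySeries(np.array([]), np.array([]), cfg))


class TestFeatureTable:
    def test_shape_and_determinism(self, small_banded):
        table = T.build_feature_table(small_banded[:4], EntropyConfig(q=3, window_w=200))
        assert len(table) == 4
        assert table.shape[1] == 4 + 62 * 5 * 2  # metadata + channel x band x stat
        again = T.build_feature_table(small_banded[:4], EntropyConfig(q=3, window_w=200))
        assert table.equals(again)

    def test_identical_trials_identical_rows(self, small_banded):
        table = T.build_feature_table(
            [small_banded[0], small_banded[0]], EntropyConfig(q=2, window_w=200)
        )
        feats = table.drop(columns=["subject", "session", "trial", "label"])
        assert feats.iloc[0].equals(feats.iloc[1])

    def test_empty_input_gives_schema_only(self):
        table = T.build_feature_table([], EntropyConfig())
        assert table.empty and list(table.columns) == ["subject", "session", "trial", "label"]

    def test_inconsistent_channels_rejected(self, small_banded, rng):
        alien = T.generate_trial(
            T.gamma_discriminative_profiles()[0], ["A1", "A2"], 200.0, 30.0, seed=1
        )
        alien_bands = T.extract_bands(alien, target_rate=None, crop_seconds=None)
        with pytest.raises(ValueError, match="channel"):
            T.build_feature_table([small_banded[0], alien_bands], EntropyConfig())
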