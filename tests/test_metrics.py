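"""Fidelity metrics against brute-force oracles and closed forms."""

import itertools

import numpy as np
import pytest

from channelsynth import (
    amplitude_histogram,
    bce_loss,
    compare_batches,
    count_amplitude_peaks,
    discriminator_loss,
    dtw_approx,
    dtw_exact,
    generator_loss,
    histogram_distance,
    mmd,
    sample_trajectory,
    two_state_model,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mmd_triple_sum(X, Y, bw):
    """Literal triple-sum unbiased MMD estimator (python loops)."""
    K = lambda a, b: np.exp(-np.sum((a - b) ** 2) / (2 * bw**2))
    n, m = len(X), len(Y)
    s_xx = sum(K(X[i], X[j]) for i in range(n) for j in range(n) if j != i)
    s_xy = sum(K(X[i], Y[j]) for i in range(n) for j in range(m))
    s_yy = sum(K(Y[i], Y[j]) for i in range(m) for j in range(m) if j != i)
    return s_xx / (n * (n - 1)) - 2 * s_xy / (m * n) + s_yy / (m * (m - 1))


def dtw_enumerate(x, y, cost):
    """Exhaustive minimum over all monotone warping paths (tiny series)."""
    N, M = len(x), len(y)
    best = [np.inf]

    def walk(i, j, acc):
        acc += cost(x[i], y[j])
        if acc >= best[0]:
            return
        if i == N - 1 and j == M - 1:
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < N and j + dj < M:
                walk(i + di, j + dj, acc)

    walk(0, 0, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# cross-entropy losses
# ---------------------------------------------------------------------------

class TestBce:
    def test_perfect_prediction_is_zero(self):
        assert bce_loss(1.0, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_coin_flip_is_log_two(self):
        assert bce_loss(0.0, 0.5) == pytest.approx(np.log(2), abs=1e-12)

    def test_batch_mean_hand_value(self):
        y = np.array([1.0, 0.0])
        p = np.array([0.9, 0.1])
        assert bce_loss(y, p) == pytest.approx(-np.log(0.9), abs=1e-12)
        assert bce_loss(y, p) == pytest.approx(0.10536, abs=1e-4)

    def test_adversarial_losses(self):
        assert discriminator_loss([1.0, 1.0], [0.0, 0.0]) == pytest.approx(0.0, abs=1e-6)
        assert generator_loss([0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-12)
        assert discriminator_loss([0.5], [0.5]) == pytest.approx(2 * np.log(2), abs=1e-12)


# ---------------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------------

class TestMmd:
    @pytest.mark.parametrize("n,m,d", [(2, 2, 1), (5, 4, 3), (10, 10, 8), (3, 10, 2)])
    def test_matches_triple_sum_oracle(self, rng, n, m, d):
        X = rng.normal(size=(n, d))
        Y = rng.normal(1.0, 1.0, size=(m, d))
        bw = 1.7
        assert mmd(X, Y, bw) == pytest.approx(mmd_triple_sum(X, Y, bw), abs=1e-12)

    def test_identical_two_point_sets(self, rng):
        v = rng.normal(size=(2, 3))
        val = mmd(v, v.copy(), 1.0)
        assert val == pytest.approx(mmd_triple_sum(v, v, 1.0), abs=1e-12)
        assert val <= 1e-12  # unbiased estimator is non-positive on X == Y

    def test_symmetric_in_arguments(self, rng):
        X = rng.normal(size=(6, 4))
        Y = rng.normal(2.0, 1.0, size=(9, 4))
        assert mmd(X, Y, 2.0) == pytest.approx(mmd(Y, X, 2.0), abs=1e-14)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(8, 4))
        Y = rng.normal(size=(7, 4))
        val = mmd(X, Y, 1.5)
        assert mmd(X[rng.permutation(8)], Y[rng.permutation(7)], 1.5) == pytest.approx(
            val, abs=1e-12
        )

    def test_separated_distributions_score_higher(self):
        # same-distribution MMD below shifted-distribution MMD in >=95/100 trials
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(50, 1))
            Y_same = r.normal(size=(50, 1))
            Y_far = r.normal(3.0, 1.0, size=(50, 1))
            bw = 1.0
            wins += abs(mmd(X, Y_same, bw)) < mmd(X, Y_far, bw)
        assert wins >= 95

    def test_input_validation(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="at least 2"):
            mmd(X[:1], X, 1.0)
        with pytest.raises(ValueError, match="bandwidth"):
            mmd(X, X, 0.0)


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

class TestDtw:
    def test_identity_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert dtw_exact(x, x) == 0.0
        assert dtw_approx(x, x) == 0.0

    def test_perfect_warp_duplicating_sample(self):
        assert dtw_exact([0, 1], [0, 1, 1], cost="absolute") == 0.0

    @pytest.mark.parametrize("cost", ["squared", "absolute"])
    def test_matches_exhaustive_path_enumeration(self, rng, cost):
        f = (lambda a, b: (a - b) ** 2) if cost == "squared" else (lambda a, b: abs(a - b))
        for N, M in itertools.product(range(1, 7), range(1, 7)):
            x = rng.integers(0, 5, N).astype(float)
            y = rng.integers(0, 5, M).astype(float)
            assert dtw_exact(x, y, cost=cost) == pytest.approx(
                dtw_enumerate(x, y, f), abs=1e-12
            )

    def test_diagonal_path_upper_bound(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        assert dtw_exact(x, y) <= np.sum((x - y) ** 2) + 1e-12

    def test_approx_equals_exact_at_full_radius(self, rng):
        for _ in range(5):
            x = rng.normal(size=33)
            y = rng.normal(size=47)
            assert dtw_approx(x, y, radius=50) == pytest.approx(
                dtw_exact(x, y), abs=1e-9
            )

    def test_approx_ratio_on_smooth_series(self, rng):
        """Approximation quality: median approx/exact <= 1.2 on smooth pairs."""
        ratios = []
        for _ in range(60):
            t = np.linspace(0, 1, 256)
            x = np.sin(2 * np.pi * rng.uniform(1, 4) * t) + 0.1 * rng.normal(size=256)
            y = np.sin(2 * np.pi * rng.uniform(1, 4) * t + rng.uniform(0, 1)) + \
                0.1 * rng.normal(size=256)
            exact = dtw_exact(x, y)
            ratios.append(dtw_approx(x, y, radius=1) / exact)
        assert np.all(np.asarray(ratios) >= 1.0 - 1e-9)  # never below exact
        assert np.median(ratios) <= 1.2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dtw_exact([], [1.0])


# ---------------------------------------------------------------------------
# amplitude histograms
# ---------------------------------------------------------------------------

class TestAmplitudeHistogram:
    def test_noiseless_record_has_two_support_points(self):
        m = two_state_model(noise_sd=0.0, filter_cutoff=None)
        rec = sample_trajectory(m, 2.0, seed=1)
        density, edges = amplitude_histogram(rec, bins=10)
        assert np.count_nonzero(density) == 2

    def test_self_distance_zero(self, demo_record):
        assert histogram_distance(demo_record, demo_record) == pytest.approx(0.0)

    def test_distance_orders_similar_before_shifted(self):
        m5 = two_state_model(unitary_current=-5.0)
        m25 = two_state_model(unitary_current=-2.5)
        a = sample_trajectory(m5, 10.0, seed=1)
        b = sample_trajectory(m5, 10.0, seed=2)
        c = sample_trajectory(m25, 10.0, seed=2)
        assert histogram_distance(a, b) < histogram_distance(a, c)

    def test_density_integrates_to_one(self, demo_record):
        density, edges = amplitude_histogram(demo_record)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_two_state_histogram_is_bimodal(self, demo_record):
        assert count_amplitude_peaks(demo_record.raw) == 2


class TestCompareBatches:
    def test_report_contents_and_determinism(self, demo_windows):
        half = demo_windows.n_windows // 2
        a = demo_windows.data[:half]
        b = demo_windows.data[half:]
        r1 = compare_batches(a, b, seed=3)
        r2 = compare_batches(a, b, seed=3)
        assert r1.mmd == r2.mmd and r1.dtw == r2.dtw
        assert 0 <= r1.histogram_distance <= 1
        assert r1.parameters["bandwidth"] > 0
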