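import numpy as np
import pytest
from scipy import stats

from nbshift.count_model import (
    THETA_CAP,
    ThetaTrend,
    estimate_mean_trimmed,
    fit_theta_mle,
    fit_theta_trend,
    nb2_variance,
    pool_bins,
    _maximize_min_tail,
    _tail_probability,
)


class TestNB2Variance:
    def test_direct_formula(self):
        assert nb2_variance(8, 2) == 40

    def test_poisson_limit(self):
        assert nb2_variance(100, 1e12) == pytest.approx(100)

    def test_zero_mean(self):
        assert nb2_variance(0, 5) == 0

    def test_rejects_nonpositive_theta(self):
        with pytest.raises(ValueError):
            nb2_variance(10, 0)


class TestPoolBins:
    def test_single_full_bin(self):
        counts = [np.array([8, 8, 8])] * 40
        bins = pool_bins(np.full(40, 8.0), counts)
        assert len(bins) == 1
        assert bins[0].n_members == 40

    def test_low_mean_excluded(self):
        counts = [np.array([7, 7, 7])] * 10 + [np.array([8, 8, 8])] * 40
        means = np.array([7.0] * 10 + [8.0] * 40)
        bins = pool_bins(means, counts)
        assert sum(b.n_members for b in bins) == 40

    def test_sparse_bins_merged_upward(self):
        counts = [np.array([8, 8, 8])] * 20 + [np.array([9, 9, 9])] * 20
        means = np.array([8.0] * 20 + [9.0] * 20)
        bins = pool_bins(means, counts)
        assert len(bins) == 1
        assert bins[0].n_members == 40

    def test_trailing_small_bin_merged_down(self):
        counts = [np.array([8, 8, 8])] * 30 + [np.array([50, 50, 50])] * 5
        means = np.array([8.0] * 30 + [50.0] * 5)
        bins = pool_bins(means, counts)
        assert len(bins) == 1
        assert bins[0].n_members == 35

    def test_no_bin_possible_raises(self):
        with pytest.raises(ValueError, match="more genes"):
            pool_bins(np.full(10, 8.0), [np.array([8, 8])] * 10)

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            pool_bins(np.full(40, 3.0), [np.array([3, 3])] * 40)


class TestThetaMLE:
    @pytest.mark.parametrize("theta", [2.0, 5.0, 20.0])
    def test_parameter_recovery(self, theta, rng):
        mu = 20.0
        x = rng.negative_binomial(theta, theta / (theta + mu), 10_000)
        est = fit_theta_mle(x)
        assert abs(est - theta) / theta < 0.1

    def test_all_equal_counts_hit_cap(self):
        assert fit_theta_mle(np.full(50, 20)) == THETA_CAP

    def test_poisson_counts_large_theta(self, rng):
        x = rng.poisson(20, 10_000)
        assert fit_theta_mle(x) >= 100

    def test_order_invariance(self, rng):
        theta, mu = 5.0, 30.0
        x = rng.negative_binomial(theta, theta / (theta + mu), 500)
        assert fit_theta_mle(x) == pytest.approx(
            fit_theta_mle(x[::-1]), rel=1e-6
        )


def _simulated_bins(rng, a=0.5, b=0.4, means=(8, 16, 32, 64, 128, 256, 512), n=5000):
    from nbshift.count_model import Bin

    bins = []
    for m in means:
        theta = np.exp(a + b * np.log(m))
        draws = rng.negative_binomial(theta, theta / (theta + m), n)
        bins.append(Bin(int(m), n // 3, draws))
    return bins


class TestThetaTrend:
    def test_coefficient_recovery(self, rng):
        bins = _simulated_bins(rng)
        fitted = fit_theta_trend(bins)
        assert fitted.intercept == pytest.approx(0.5, abs=0.1)
        assert fitted.slope == pytest.approx(0.4, abs=0.1)

    def test_flat_trend(self):
        from nbshift.count_model import Bin

        bins = [
            Bin(8, 30, np.full(30, 8), theta=5.0),
            Bin(60, 30, np.full(30, 60), theta=5.0),
        ]
        fitted = fit_theta_trend(bins)
        assert fitted.predict_theta(10.0) == pytest.approx(5.0)
        assert fitted.predict_theta(50.0) == pytest.approx(5.0)

    def test_positive_and_continuous(self, trend):
        mus = np.linspace(1.0, 3000.0, 500)
        thetas = trend.predict_theta(mus)
        assert np.all(thetas > 0)
        assert np.max(np.abs(np.diff(thetas))) < 1.0  # no jumps on a fine grid

    def test_clamped_outside_range(self, trend):
        assert trend.predict_theta(1.0) == trend.predict_theta(trend.mu_min)
        assert trend.predict_theta(1e9) == trend.predict_theta(trend.mu_max)

    def test_requires_two_bins(self):
        from nbshift.count_model import Bin

        with pytest.raises(ValueError):
            fit_theta_trend([Bin(8, 30, np.full(30, 8), theta=5.0)])

    def test_json_round_trip(self, trend):
        restored = ThetaTrend.from_json(trend.to_json())
        assert restored.predict_theta(50.0) == trend.predict_theta(50.0)


class TestTrimmedMean:
    def test_symmetric_case(self, trend):
        est = estimate_mean_trimmed([10, 10, 10], trend)
        assert est.mean == pytest.approx(10.0, rel=1e-3)
        assert est.retained == 3
        assert est.outlier_indices == []
        assert not est.excluded

    def test_single_outlier_removed(self, trend):
        # tail probability of 400 under NB2(~11, theta(11)) is far below 0.05
        theta = trend.predict_theta(11.0)
        tail = stats.nbinom.sf(399, theta, theta / (theta + 11.0))
        assert tail < 0.05
        est = estimate_mean_trimmed([10, 12, 400], trend)
        assert est.outlier_indices == [2]
        assert est.retained == 2
        assert not est.excluded
        assert est.mean == pytest.approx(11.0, rel=0.15)

    def test_two_outliers_excluded(self, trend):
        est = estimate_mean_trimmed([1, 100, 10000], trend)
        assert est.excluded

    def test_three_replicates_at_most_one_removal(self, trend, rng):
        for _ in range(50):
            counts = rng.integers(0, 500, size=3)
            est = estimate_mean_trimmed(counts, trend)
            assert len(est.outlier_indices) <= 1

    def test_retained_plus_removed_equals_total(self, trend, rng):
        for _ in range(20):
            counts = rng.integers(0, 200, size=4)
            est = estimate_mean_trimmed(counts, trend)
            if not est.excluded:
                assert est.retained + len(est.outlier_indices) == 4

    def test_agrees_with_brute_force_grid(self, trend, rng):
        # oracle: dense grid search of the min-tail objective
        for _ in range(10):
            counts = np.sort(rng.integers(8, 120, size=3))
            grid = np.linspace(counts.min(), counts.max(), 4001)
            obj = _tail_probability(counts, grid, trend).min(axis=1)
            oracle_mu = grid[np.argmax(obj)]
            mu, _ = _maximize_min_tail(counts, trend)
            span = counts.max() - counts.min()
            if span == 0:
                assert mu == counts[0]
            else:
                # both must achieve (numerically) the same objective value
                ours = _tail_probability(counts, mu, trend).min()
                best = obj.max()
                assert ours >= best - 1e-4

    def test_retained_counts_pass_after_trim(self, trend, rng):
        # after re-estimation, every retained count has tail prob >= alpha,
        # or the gene is excluded
        for _ in range(30):
            counts = rng.integers(0, 1000, size=3)
            est = estimate_mean_trimmed(counts, trend)
            if est.excluded:
                continue
            kept = np.delete(counts, est.outlier_indices)
            tails = _tail_probability(kept, est.mean, trend)
            assert np.all(tails >= 0.05 - 1e-9)

    def test_requires_two_counts(self, trend):
        with pytest.raises(ValueError):
            estimate_mean_trimmed([5], trend)
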