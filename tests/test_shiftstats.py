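import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbshift.shiftstats import (
    cumulative_shift,
    differential_set_activity,
    diurnal_variance,
    floor_log2,
    permutation_test,
    set_activity,
    standardize_expression,
)
from conftest import brute_force_shift

samples = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=1, max_size=60
)


class TestCumulativeShift:
    def test_identical_samples_zero(self):
        a = [1.0, 2.0, 5.0]
        assert cumulative_shift(a, a) == 0.0

    def test_positive_for_shifted_sample(self, rng):
        a = rng.normal(0, 1, 100)
        assert cumulative_shift(a, a + 3.0) > 0

    @given(samples, samples)
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry(self, a, b):
        assert cumulative_shift(a, b) == pytest.approx(-cumulative_shift(b, a))

    @given(samples, samples)
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, a, b):
        assert cumulative_shift(a, b) == pytest.approx(brute_force_shift(a, b))

    def test_matches_brute_force_large(self, rng):
        for _ in range(5):
            a = rng.integers(0, 50, size=rng.integers(10, 200)).astype(float)
            b = rng.integers(0, 50, size=rng.integers(10, 200)).astype(float)
            assert cumulative_shift(a, b) == pytest.approx(brute_force_shift(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cumulative_shift([], [1.0])


class TestPermutationTest:
    def test_identical_samples_p_near_one(self, rng):
        a = rng.normal(0, 1, 40)
        res = permutation_test(a, a, seed=0, n_permutations=2000)
        assert res.p_exact > 0.5
        assert res.shift == 0.0

    def test_separated_samples_floored(self, rng):
        a = rng.normal(0, 1, 100)
        res = permutation_test(a, a + 100.0, seed=0)
        assert res.p_exact == 1e-4

    def test_floor_respected_all_modes(self, rng):
        a = rng.normal(0, 1, 80)
        for paired in (False, True):
            for side in ("one", "two"):
                res = permutation_test(
                    a, a + 50.0, sidedness=side, seed=1, paired=paired,
                    n_permutations=500,
                )
                assert res.p_exact >= 1.0 / 500

    def test_null_matches_explicit_relabeling(self, rng):
        # the linear subset-sum trick must agree with literally permuting
        # labels and recomputing ECDFs
        a = rng.integers(0, 20, 12).astype(float)
        b = rng.integers(0, 20, 15).astype(float)
        pooled = np.concatenate([a, b])
        explicit = []
        rng2 = np.random.default_rng(99)
        for _ in range(300):
            perm = rng2.permutation(pooled)
            explicit.append(cumulative_shift(perm[:12], perm[12:]))
        res = permutation_test(a, b, seed=3, n_permutations=2000)
        # same support and comparable spread
        assert np.std(explicit) == pytest.approx(
            _null_std(a, b, seed=3), rel=0.25
        )
        assert res.n_permutations == 2000

    def test_paired_null_matches_explicit_swaps(self, rng):
        a = rng.integers(0, 30, 20).astype(float)
        b = rng.integers(0, 30, 20).astype(float)
        rng2 = np.random.default_rng(7)
        explicit = []
        for _ in range(400):
            s = rng2.integers(0, 2, 20).astype(bool)
            aa = np.where(s, b, a)
            bb = np.where(s, a, b)
            explicit.append(cumulative_shift(aa, bb))
        stat = _paired_null_samples(a, b, 400, seed=7)
        assert np.mean(explicit) == pytest.approx(np.mean(stat), abs=0.5)
        assert np.std(explicit) == pytest.approx(np.std(stat), rel=0.25)

    def test_two_sided_calibration(self, rng):
        # under the null, P(p <= alpha) <= alpha + 0.02
        reps = 500
        pvals = np.empty(reps)
        for i in range(reps):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            pvals[i] = permutation_test(
                x, y, seed=int(rng.integers(2**31)), n_permutations=400
            ).p_exact
        for alpha in (0.01, 0.05, 0.1):
            assert np.mean(pvals <= alpha) <= alpha + 0.02

    def test_invalid_sidedness(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0], sidedness="three")


def _null_std(a, b, seed):
    res = []
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    for _ in range(2000):
        perm = rng.permutation(pooled)
        res.append(cumulative_shift(perm[: len(a)], perm[len(a):]))
    return np.std(res)


def _paired_null_samples(a, b, n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        s = rng.integers(0, 2, len(a)).astype(bool)
        out.append(cumulative_shift(np.where(s, b, a), np.where(s, a, b)))
    return np.array(out)


class TestDiurnalVariance:
    def test_flat_genes_zero(self):
        x = np.full((20, 4), 50.0)
        variances, _, _ = diurnal_variance(x)
        assert np.allclose(variances, 0.0)

    def test_single_point_shift_algebra(self):
        # shifting one of 4 points by d moves that point (3d/4)^2 and the
        # others (d/4)^2 away from the per-gene mean
        d = 4.0
        x = np.full((50, 4), 10.0)
        x[:, 1] += d
        variances, _, _ = diurnal_variance(x, already_log=True)
        assert variances[1] == pytest.approx((3 * d / 4) ** 2)
        for t in (0, 2, 3):
            assert variances[t] == pytest.approx((d / 4) ** 2)

    def test_flooring_applied(self):
        x = np.full((5, 4), 2.0)  # all below the floor of 8
        variances, _, _ = diurnal_variance(x)
        assert np.allclose(variances, 0.0)

    def test_ranking_follows_injected_structure(self, rng):
        x = 2.0 ** rng.normal(6, 0.1, size=(300, 4))
        x[:, 3] *= 2.0 ** rng.normal(0, 1.5, size=300)  # big spread at t=3
        variances, _, _ = diurnal_variance(x)
        assert np.argmax(variances) == 3


class TestSetActivity:
    def test_flat_set_shift_zero(self):
        vals = np.full((120, 4), 40.0)
        res = set_activity(vals, 0, seed=0, n_permutations=500)
        assert res.shift == 0.0
        assert res.p_exact > 0.5

    def test_small_set_not_tested(self, rng):
        vals = rng.uniform(8, 100, (99, 4))
        assert set_activity(vals, 0, seed=0) is None

    def test_injected_overexpression_detected(self, rng):
        vals = rng.uniform(20, 60, (150, 4))
        vals[:, 2] *= 2.0
        res = set_activity(vals, 2, seed=0)
        assert res.shift > 0
        assert res.p_exact <= 0.01

    def test_shifts_roughly_conserve(self, rng):
        # the four per-point shifts of one set against the pooled rest sum
        # to ~0 on exchangeable data
        vals = rng.uniform(10, 100, (150, 4))
        shifts = [
            set_activity(vals, t, seed=t, n_permutations=100).shift
            for t in range(4)
        ]
        scale = np.abs(shifts).max()
        assert abs(sum(shifts)) < max(scale, 1.0) * 0.75


class TestDifferentialSetActivity:
    def test_identical_lines_zero(self, rng):
        vals = rng.uniform(8, 80, 120)
        res = differential_set_activity(vals, vals, seed=0, n_permutations=500)
        assert res.shift == 0.0

    def test_doubled_line_positive(self, rng):
        vals = rng.uniform(8, 80, 150)
        res = differential_set_activity(vals, vals * 2, seed=0)
        assert res.shift > 0
        assert res.p_exact <= 0.01

    def test_antisymmetric_in_line_order(self, rng):
        a = rng.uniform(8, 80, 120)
        b = a * rng.uniform(0.5, 2.0, 120)
        r1 = differential_set_activity(a, b, seed=0, n_permutations=200)
        r2 = differential_set_activity(b, a, seed=0, n_permutations=200)
        assert r1.shift == pytest.approx(-r2.shift)

    def test_small_set_skipped(self, rng):
        vals = rng.uniform(8, 80, 50)
        assert differential_set_activity(vals, vals * 2, seed=0) is None


class TestStandardize:
    def test_constant_profile_zero(self):
        assert np.allclose(standardize_expression(np.array([8.0, 8, 8, 8])), 0.0)

    def test_zero_mean_unit_sd(self, rng):
        x = rng.uniform(1, 100, (30, 4))
        z = standardize_expression(x)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0)

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=4).filter(
            lambda v: max(v) - min(v) > 1e-6
        ),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, profile, scale, offset):
        x = np.array(profile)
        assert standardize_expression(x * scale + offset) == pytest.approx(
            standardize_expression(x), abs=1e-6
        )


def test_floor_log2():
    assert np.allclose(floor_log2([4, 8, 16]), [3.0, 3.0, 4.0])
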