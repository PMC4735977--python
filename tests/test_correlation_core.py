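import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coexpmi import (
    JointCountTable,
    adaptive_bins,
    entropy,
    fixed_interval_bins,
    joint_counts,
    mi_adaptive,
    mutual_information,
    pearson_r,
)
from coexpmi.errors import (
    DegenerateInputError,
    InsufficientSamplesError,
    InvalidBinningError,
    LengthMismatchError,
    OutOfRangeError,
    ZeroVarianceError,
)


class TestPearson:
    def test_five_point_worked_examples(self, five_point_linear, five_point_shuffled):
        x, y = five_point_linear
        assert pearson_r(x, y) == pytest.approx(0.8, abs=1e-12)
        x, y = five_point_shuffled
        assert pearson_r(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_identity_and_symmetry(self):
        v = np.array([1.0, 5.0, 2.0, 8.0])
        w = np.array([2.0, 1.0, 9.0, 4.0])
        assert pearson_r(v, v) == pytest.approx(1.0, abs=1e-12)
        assert pearson_r(v, w) == pearson_r(w, v)

    def test_zero_variance_is_an_error_not_zero(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            pearson_r(np.arange(3.0), np.arange(4.0))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=3, max_size=30
        ),
        a=st.floats(0.1, 10),
        b=st.floats(0, 50),
    )
    def test_affine_rescaling_invariance(self, data, a, b):
        x = np.array([p[0] for p in data])
        y = np.array([p[1] for p in data])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r = pearson_r(x, y)
        assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-9)


class TestFixedIntervalBins:
    def test_five_equally_spaced_values_one_per_bin(self, five_point_linear):
        x, _ = five_point_linear
        scheme = fixed_interval_bins(x, 5, 0.0, 1.0)
        assert scheme.labels.tolist() == [0, 1, 2, 3, 4]
        assert scheme.counts.tolist() == [1, 1, 1, 1, 1]

    def test_identical_values_fill_one_bin(self):
        scheme = fixed_interval_bins(np.full(7, 0.5), 3, 0.0, 1.0)
        assert sorted(scheme.counts.tolist()) == [0, 0, 7]

    def test_right_edge_belongs_to_last_bin(self):
        scheme = fixed_interval_bins(np.array([0.0, 1.0]), 5, 0.0, 1.0)
        assert scheme.labels.tolist() == [0, 4]

    def test_interior_boundary_goes_to_upper_bin(self):
        scheme = fixed_interval_bins(np.array([0.2, 0.1]), 5, 0.0, 1.0)
        assert scheme.labels.tolist() == [1, 0]

    def test_errors(self):
        with pytest.raises(OutOfRangeError):
            fixed_interval_bins(np.array([0.5, 1.5]), 5, 0.0, 1.0)
        with pytest.raises(InvalidBinningError):
            fixed_interval_bins(np.array([0.5, 0.6]), 1)


class TestAdaptiveBins:
    def test_divisible_case_is_exactly_equal_frequency(self):
        rng = np.random.default_rng(0)
        v = rng.permutation(22).astype(float)
        scheme = adaptive_bins(v, 11)
        assert scheme.counts.tolist() == [2] * 11

    def test_thousand_uniforms_floor_or_ceil_of_n_over_m(self):
        v = np.random.default_rng(123).uniform(size=1000)
        counts = adaptive_bins(v, 11).counts
        assert set(counts.tolist()) <= {90, 91}
        assert counts.sum() == 1000

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientSamplesError):
            adaptive_bins(np.arange(5.0), 11)

    def test_too_few_distinct_values(self):
        with pytest.raises(DegenerateInputError):
            adaptive_bins(np.array([1.0, 1.0, 2.0, 2.0, 3.0] * 4), 11)

    def test_ties_never_split_across_bins(self):
        v = np.array([0.0, 1.0, 2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        scheme = adaptive_bins(v, 5)
        labels_of_ties = scheme.labels[v == 3.0]
        assert len(set(labels_of_ties.tolist())) == 1
        assert scheme.counts.sum() == 10

    def test_bins_cover_range_without_overlap(self):
        v = np.random.default_rng(5).normal(size=217)
        scheme = adaptive_bins(v, 11)
        b = scheme.boundaries
        assert np.all(np.diff(b) > 0)
        assert b[0] == v.min() and b[-1] == v.max()
        # every sample gets exactly one label consistent with its interval
        for value, lab in zip(v, scheme.labels):
            assert b[lab] <= value <= b[lab + 1]


class TestEntropy:
    def test_single_occupied_bin_has_zero_entropy(self):
        scheme = fixed_interval_bins(np.full(9, 0.2), 3, 0.0, 1.0)
        assert entropy(scheme) == 0.0

    def test_balanced_bins_reach_log2_m(self):
        scheme = fixed_interval_bins(np.arange(22.0), 11, 0.0, 22.0)
        assert entropy(scheme) == pytest.approx(np.log2(11), abs=1e-12)
        assert entropy(scheme) == pytest.approx(3.4594, abs=5e-5)


class TestJointCountsAndMI:
    def test_worked_examples_are_permutation_tables(self, five_point_linear,
                                                    five_point_shuffled, fixed5):
        for x, y in (five_point_linear, five_point_shuffled):
            table = joint_counts(fixed5.bins(x), fixed5.bins(y))
            assert table.counts.sum() == 5
            assert np.all(table.counts.sum(axis=0) == 1)
            assert np.all(table.counts.sum(axis=1) == 1)
        # the two arrangements give *different* permutation matrices
        t1 = joint_counts(fixed5.bins(five_point_linear[0]), fixed5.bins(five_point_linear[1]))
        t2 = joint_counts(fixed5.bins(five_point_shuffled[0]), fixed5.bins(five_point_shuffled[1]))
        assert not np.array_equal(t1.counts, t2.counts)

    def test_worked_example_mi_value(self, five_point_linear, five_point_shuffled, fixed5):
        """Both arrangements carry the identical 2.322 bits: rearranging the
        points destroys r but not predictability."""
        for x, y in (five_point_linear, five_point_shuffled):
            mi = fixed5.mi(x, y)
            assert round(mi, 3) == 2.322
            assert mi == pytest.approx(np.log2(5), abs=1e-12)

    def test_factorizing_table_has_zero_mi(self):
        table = JointCountTable(counts=np.ones((2, 2), dtype=int))
        assert mutual_information(table) == 0.0

    def test_transpose_symmetry_and_entropy_identity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        sx, sy = adaptive_bins(x, 7), adaptive_bins(y, 9)
        table = joint_counts(sx, sy)
        mi = mutual_information(table)
        assert mi == pytest.approx(
            mutual_information(JointCountTable(counts=table.counts.T)), abs=1e-12
        )
        # joint entropy from the table, marginals from the schemes
        p = table.counts[table.counts > 0] / table.n
        h_xy = -(p * np.log2(p)).sum()
        assert mi == pytest.approx(entropy(sx) + entropy(sy) - h_xy, abs=1e-10)
        assert 0.0 <= mi <= min(np.log2(7), np.log2(9))

    def test_marginals_match_schemes(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(size=100), rng.uniform(size=100)
        sx, sy = adaptive_bins(x, 5), adaptive_bins(y, 11)
        table = joint_counts(sx, sy)
        np.testing.assert_array_equal(table.row_marginals, sx.counts)
        np.testing.assert_array_equal(table.col_marginals, sy.counts)

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            joint_counts(
                fixed_interval_bins(np.arange(4.0), 2),
                fixed_interval_bins(np.arange(5.0), 2),
            )

    def test_brute_force_plugin_oracle_small_n(self):
        """For N <= 12, the closed-form MI must match a naive -sum(p log p)
        enumeration over occupied cells."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(2, 13))
            mx, my = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            lx = rng.integers(0, mx, size=n)
            ly = rng.integers(0, my, size=n)
            counts = np.zeros((mx, my), dtype=int)
            for a, b in zip(lx, ly):
                counts[a, b] += 1
            # oracle: plug-in entropies by direct dictionary enumeration
            def h(items):
                from collections import Counter
                freq = Counter(items)
                return -sum((c / n) * np.log2(c / n) for c in freq.values())
            oracle = h(lx.tolist()) + h(ly.tolist()) - h(list(zip(lx, ly)))
            assert mutual_information(JointCountTable(counts=counts)) == pytest.approx(
                max(oracle, 0.0), abs=1e-10
            )


class TestMIAdaptive:
    def test_monotone_bijection_reaches_log2_m(self):
        x = np.random.default_rng(1).permutation(11 * 8).astype(float)
        y = np.exp(x / 50.0)  # strictly monotone bijection
        assert mi_adaptive(x, y, 11) == pytest.approx(np.log2(11), abs=1e-12)

    def test_independent_large_sample_mi_is_small(self):
        rng = np.random.default_rng(77)
        x, y = rng.uniform(size=10_000), rng.uniform(size=10_000)
        assert mi_adaptive(x, y, 11) < 0.1  # finite-sample bias only

    def test_constant_profile_rejected(self):
        with pytest.raises(DegenerateInputError):
            mi_adaptive(np.ones(100), np.random.default_rng(0).uniform(size=100))

    def test_joint_shuffle_leaves_mi_and_r_unchanged(self):
        rng = np.random.default_rng(31)
        x, y = rng.uniform(size=500), None
        y = x ** 2 + rng.normal(0, 0.05, 500).clip(-0.2, 0.2)
        perm = rng.permutation(500)
        assert mi_adaptive(x[perm], y[perm]) == pytest.approx(mi_adaptive(x, y), abs=1e-12)
        assert pearson_r(x[perm], y[perm]) == pytest.approx(pearson_r(x, y), abs=1e-12)

    def test_marginal_shuffle_destroys_dependency(self):
        rng = np.random.default_rng(32)
        x = rng.uniform(size=2000)
        y = x ** 3 + rng.normal(0, 0.02, 2000)
        y = np.clip(y, 0, None)
        mi_dep = mi_adaptive(x, y)
        y_shuffled = y[rng.permutation(2000)]
        assert mi_adaptive(x, y_shuffled) < 0.2 < mi_dep
        assert abs(pearson_r(x, y_shuffled)) < 0.1 < abs(pearson_r(x, y))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    counts=st.lists(
        st.lists(st.integers(0, 6), min_size=2, max_size=4),
        min_size=2, max_size=4,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1 and sum(map(sum, rows)) > 0)
)
def test_mi_is_nonnegative_symmetric_and_bounded(counts):
    table = JointCountTable(counts=np.array(counts))
    mi = mutual_information(table)
    assert mi >= 0.0
    assert mi == pytest.approx(
        mutual_information(JointCountTable(counts=table.counts.T)), abs=1e-12
    )
    mx, my = table.counts.shape
    assert mi <= min(np.log2(mx), np.log2(my)) + 1e-12
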