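"""Community statistics: normalization, representatives, correlation, overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pneumotyper.stats import (
    abundance_report,
    correlation_to_profile,
    group_correlation,
    leave_one_out_correlation,
    log2_transform,
    overlap,
    overlap_matrix,
    representative_profile,
    to_proportions,
)
from _oracles import overlap_bruteforce


def _frame(rows, genera=None):
    arr = np.asarray(rows)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=genera or [f"g{j}" for j in range(arr.shape[1])],
    )


count_matrices = arrays(
    np.int64,
    st.tuples(st.integers(2, 8), st.integers(2, 10)),
    elements=st.integers(0, 50),
)


class TestProportions:
    def test_simple_row(self):
        props = to_proportions(_frame([[10, 30]]))
        assert list(props.iloc[0]) == [25.0, 75.0]

    def test_zero_row_flagged_and_preserved(self):
        props = to_proportions(_frame([[0, 0], [1, 1]]))
        assert list(props.iloc[0]) == [0.0, 0.0]
        assert props.attrs["zero_samples"] == ["s0"]

    @given(count_matrices)
    def test_row_sums_are_zero_or_hundred(self, mat):
        sums = to_proportions(_frame(mat)).sum(axis=1)
        assert all(abs(s) < 1e-9 or abs(s - 100) < 1e-9 for s in sums)


class TestLog2:
    def test_values(self):
        out = log2_transform(_frame([[0, 7]]))
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(3.0)

    def test_monotone(self):
        out = log2_transform(_frame([[2, 9, 100]]))
        assert out.iloc[0].is_monotonic_increasing

    def test_rejects_nonpositive_pseudocount(self):
        with pytest.raises(ValueError):
            log2_transform(_frame([[1]]), pseudocount=0)


class TestRepresentative:
    def test_singleton_group_equals_its_row(self):
        log2 = log2_transform(_frame([[3, 4], [9, 1]]))
        prof = representative_profile(log2, ["s0"])
        assert prof.values.equals(log2.loc["s0"].rename(prof.values.name))

    def test_mean_of_two_members(self):
        log2 = log2_transform(_frame([[1], [7]]))
        prof = representative_profile(log2, ["s0", "s1"])
        assert prof.values.iloc[0] == pytest.approx(2.0)  # mean of log2(2), log2(8)

    def test_member_order_irrelevant(self):
        log2 = log2_transform(_frame([[1, 5], [7, 2], [3, 3]]))
        a = representative_profile(log2, ["s0", "s1", "s2"]).values
        b = representative_profile(log2, ["s2", "s0", "s1"]).values
        assert a.equals(b)

    def test_empty_members_error(self):
        with pytest.raises(ValueError):
            representative_profile(log2_transform(_frame([[1]])), [])


class TestCorrelation:
    def test_self_singleton_is_one(self):
        log2 = log2_transform(_frame([[3, 9, 1, 4]]))
        prof = representative_profile(log2, ["s0"])
        assert correlation_to_profile(log2.loc["s0"], prof) == pytest.approx(1.0)

    def test_genus_order_invariance(self):
        log2 = log2_transform(_frame([[3, 9, 1, 4], [2, 8, 3, 3]]))
        prof = representative_profile(log2, ["s1"])
        c1 = correlation_to_profile(log2.loc["s0"], prof)
        shuffled = log2.loc["s0"].iloc[[2, 0, 3, 1]]
        assert correlation_to_profile(shuffled, prof) == pytest.approx(c1)

    def test_constant_vector_errors(self):
        log2 = log2_transform(_frame([[1, 1, 1], [2, 5, 9]]))
        prof = representative_profile(log2, ["s1"])
        with pytest.raises(ValueError, match="constant"):
            correlation_to_profile(log2.loc["s0"], prof)

    def test_spearman_option(self):
        log2 = log2_transform(_frame([[1, 2, 4], [1, 3, 9]]))
        prof = representative_profile(log2, ["s1"])
        assert correlation_to_profile(
            log2.loc["s0"], prof, method="spearman"
        ) == pytest.approx(1.0)

    def test_group_mean_equals_mean_of_per_sample(self):
        log2 = log2_transform(_frame(np.arange(12).reshape(3, 4)))
        prof = representative_profile(log2, list(log2.index))
        mean, per_sample = group_correlation(log2, list(log2.index), prof)
        assert mean == pytest.approx(per_sample.mean())

    def test_identical_samples_give_intra_correlation_one(self):
        log2 = log2_transform(_frame([[3, 9, 1], [3, 9, 1]]))
        prof = representative_profile(log2, list(log2.index))
        mean, _ = group_correlation(log2, list(log2.index), prof)
        assert mean == pytest.approx(1.0)

    def test_disjoint_support_cross_below_intra(self):
        rng = np.random.default_rng(0)
        a = rng.integers(50, 200, size=(5, 4))
        mat = np.zeros((10, 8), dtype=int)
        mat[:5, :4] = a
        mat[5:, 4:] = rng.integers(50, 200, size=(5, 4))
        log2 = log2_transform(_frame(mat))
        group_a = [f"s{i}" for i in range(5)]
        group_b = [f"s{i}" for i in range(5, 10)]
        prof_a = representative_profile(log2, group_a)
        intra, _ = group_correlation(log2, group_a, prof_a)
        cross, _ = group_correlation(log2, group_b, prof_a)
        assert cross < intra

    def test_leave_one_out_below_or_close_to_inclusive(self):
        rng = np.random.default_rng(1)
        log2 = log2_transform(_frame(rng.integers(0, 100, size=(6, 5))))
        members = list(log2.index)
        prof = representative_profile(log2, members)
        inclusive, _ = group_correlation(log2, members, prof)
        loo, _ = leave_one_out_correlation(log2, members)
        assert loo <= inclusive + 1e-9


class TestOverlap:
    def test_single_genus_in_both_samples_is_100(self):
        counts = _frame([[10], [3]])
        assert overlap(counts, ["s0", "s1"]) == pytest.approx(100.0)

    def test_half_cooccurrence_is_50(self):
        counts = _frame([[10, 0], [0, 10]])
        assert overlap(counts, ["s0", "s1"]) == pytest.approx(50.0)

    def test_disjoint_groups_are_0(self):
        counts = _frame([[5, 0], [0, 7]])
        assert overlap(counts, ["s0"], ["s1"]) == 0.0

    def test_symmetry_and_bounds(self, random_counts):
        a = list(random_counts.index[:4])
        b = list(random_counts.index[4:])
        ab = overlap(random_counts, a, b)
        ba = overlap(random_counts, b, a)
        assert ab == pytest.approx(ba)
        assert 0 <= ab <= 100

    def test_intra_overlap_100_iff_full_cooccurrence(self):
        full = _frame([[1, 2], [3, 4]])
        assert overlap(full, list(full.index)) == pytest.approx(100.0)
        partial = _frame([[1, 0], [3, 4]])
        assert overlap(partial, list(partial.index)) < 100.0

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 20))
            g = int(rng.integers(2, 30))
            mat = rng.integers(0, 30, size=(n, g))
            mat[rng.random(mat.shape) < 0.4] = 0
            counts = _frame(mat)
            if counts.to_numpy().sum() == 0:
                continue
            split = int(rng.integers(1, n))
            a = list(counts.index[:split])
            b = list(counts.index[split:])
            if counts.loc[a + b].to_numpy().sum() == 0:
                continue
            assert overlap(counts, a, b) == pytest.approx(
                overlap_bruteforce(counts, a, b)
            )
            assert overlap(counts, a, a) == pytest.approx(
                overlap_bruteforce(counts, a, a)
            )

    def test_literal_variant_scales_like_inverse_n(self):
        counts = _frame([[10], [10], [10], [10]])
        members = list(counts.index)
        assert overlap(counts, members, literal=True) == pytest.approx(
            overlap(counts, members) / len(members)
        )

    def test_zero_pool_errors(self):
        with pytest.raises(ValueError):
            overlap(_frame([[0], [0]]), ["s0", "s1"])

    def test_matrix_diagonal_is_intra(self, random_counts):
        groups = {
            "A": list(random_counts.index[:4]),
            "B": list(random_counts.index[4:]),
        }
        mat = overlap_matrix(random_counts, groups)
        assert mat.loc["A", "A"] == pytest.approx(
            overlap(random_counts, groups["A"])
        )
        assert mat.loc["A", "B"] == pytest.approx(mat.loc["B", "A"])


class TestAbundanceReport:
    def test_identical_samples_report_their_proportions(self):
        counts = _frame([[60, 39, 1], [60, 39, 1]])
        report = abundance_report(counts, {"grp": ["s0", "s1"]})
        assert report.loc["g0", "grp"] == pytest.approx(60.0)
        assert report.loc["g1", "grp"] == pytest.approx(39.0)

    def test_genus_below_threshold_everywhere_suppressed(self):
        counts = _frame([[995, 5], [995, 5]])  # g1 at 0.5%
        report = abundance_report(counts, {"grp": ["s0", "s1"]}, threshold=1.0)
        assert "g1" not in report.index

    def test_zero_threshold_lists_all_detected(self):
        counts = _frame([[10, 1, 0]])
        report = abundance_report(counts, {"grp": ["s0"]}, threshold=0.0)
        assert set(report.index) == {"g0", "g1"}
        assert np.isnan(report.loc["g0"].get("missing", np.nan))

    def test_undetected_cell_is_nan(self):
        counts = _frame([[100, 0], [0, 100]])
        report = abundance_report(
            counts, {"A": ["s0"], "B": ["s1"]}, threshold=1.0
        )
        assert np.isnan(report.loc["g0", "B"])
        assert report.loc["g0", "A"] == pytest.approx(100.0)
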