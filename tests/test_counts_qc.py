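import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import sctagdiff as st
from sctagdiff.errors import ConfigurationError, PipelineError
from sctagdiff.io import Fragment, Peak


def matrix_from_dense(dense, n_bins=2, **kw):
    dense = np.asarray(dense, dtype=float)
    return st.BinnedCountMatrix(
        counts=sparse.csr_matrix(dense),
        cell_ids=[f"c{i}" for i in range(dense.shape[0])],
        peak_ids=[f"p{i}" for i in range(dense.shape[1] // n_bins)],
        n_bins=n_bins,
        **kw,
    )


class TestBuildMatrix:
    @pytest.fixture()
    def setup(self):
        peaks = [Peak("chr1", 9950, 10050, "p1", 1000)]
        windows = st.make_windows(peaks)
        design = pd.DataFrame(
            {"barcode": ["c1", "c2", "c3"], "condition": ["A", "A", "B"]}
        )
        return windows, design

    def test_total_conserved_in_midpoint_mode(self, setup):
        windows, design = setup
        frags = [
            Fragment("chr1", 7500, 7560, "c1"),
            Fragment("chr1", 9000, 9080, "c2"),
            Fragment("chr1", 12_400, 12_480, "c3"),
        ]
        mats = st.build_matrix(frags, windows, design)
        assert mats["A"].counts.sum() + mats["B"].counts.sum() == 3

    def test_unknown_barcode_dropped_with_warning(self, setup):
        windows, design = setup
        frags = [Fragment("chr1", 7500, 7560, "nope")]
        with pytest.warns(UserWarning, match="absent from the design"):
            mats = st.build_matrix(frags, windows, design)
        assert mats["A"].counts.sum() == 0

    def test_conditions_share_column_order_and_zero_rows(self, setup):
        windows, design = setup
        mats = st.build_matrix([], windows, design)
        assert list(mats["A"].peak_ids) == list(mats["B"].peak_ids)
        assert mats["A"].n_cells == 2 and mats["B"].n_cells == 1

    def test_vectorised_and_generic_paths_agree(self, small_sim):
        peaks = st.filter_peaks(small_sim.peaks)
        ws = st.make_windows(peaks, chrom_sizes=small_sim.chrom_sizes)
        frags = small_sim.all_fragments()
        fast = st.build_matrix(frags, ws, small_sim.design)  # disjoint -> fast
        frag_objs = [
            Fragment(r.chrom, r.start, r.end, r.barcode, r.count)
            for r in frags.itertuples(index=False)
        ]
        slow = st.build_matrix(frag_objs, ws, small_sim.design, mode="overlap")
        # midpoint fast path vs per-fragment loop in midpoint mode
        slow_mid = st.build_matrix(iter(frag_objs), ws, small_sim.design)
        for cond in fast:
            assert (fast[cond].counts != slow_mid[cond].counts).nnz == 0
            assert slow[cond].counts.sum() >= fast[cond].counts.sum()


class TestReadFilter:
    def test_strictly_greater_than_threshold(self):
        dense = np.zeros((2, 4))
        dense[0, 0] = 250   # exactly at threshold: removed
        dense[1, 0] = 251
        kept = st.filter_cells_by_reads(matrix_from_dense(dense), min_reads=250)
        assert list(kept.cell_ids) == ["c1"]

    def test_zero_threshold_keeps_any_read(self):
        dense = np.array([[0.0, 0, 0, 0], [1, 0, 0, 0]])
        kept = st.filter_cells_by_reads(matrix_from_dense(dense), min_reads=0)
        assert list(kept.cell_ids) == ["c1"]

    def test_all_removed_is_error(self):
        with pytest.raises(PipelineError, match="threshold"):
            st.filter_cells_by_reads(
                matrix_from_dense(np.zeros((2, 4))), min_reads=250
            )

    def test_idempotent(self, rng):
        dense = rng.poisson(5, (30, 8)).astype(float)
        once = st.filter_cells_by_reads(matrix_from_dense(dense), min_reads=30)
        twice = st.filter_cells_by_reads(once, min_reads=30)
        assert list(once.cell_ids) == list(twice.cell_ids)


class TestQuantileFilter:
    def test_100_distinct_cells_keep_80(self):
        # one cell per non-zero-peak value 1..100 -> 15 low + 5 high removed
        n_bins = 1
        dense = np.zeros((100, 100))
        for i in range(100):
            dense[i, : i + 1] = 1
        mat = matrix_from_dense(dense, n_bins=n_bins)
        kept = st.quantile_filter_cells(mat, lower=0.15, upper=0.05)
        assert kept.n_cells == 80
        values = kept.nonzero_peaks_per_cell()
        assert values.min() == 16 and values.max() == 95

    def test_zero_fractions_are_identity(self):
        dense = np.diag(np.arange(1, 6)).astype(float)
        mat = matrix_from_dense(dense, n_bins=1)
        assert st.quantile_filter_cells(mat, 0, 0).n_cells == 5

    def test_invalid_fractions_rejected(self):
        mat = matrix_from_dense(np.ones((3, 4)))
        with pytest.raises(ConfigurationError):
            st.quantile_filter_cells(mat, lower=0.6, upper=0.5)


class TestNormalizeAndLog:
    def test_scaling_factor(self):
        dense = np.array([[3.0, 0, 497, 0]])
        scaled = st.normalize_total(matrix_from_dense(dense), target=10_000)
        assert scaled.counts[0, 0] == pytest.approx(60.0)

    def test_non_empty_rows_sum_to_target(self, rng):
        dense = rng.poisson(2, (20, 10)).astype(float)
        dense[3] = 0
        scaled = st.normalize_total(matrix_from_dense(dense, n_bins=5))
        totals = scaled.cell_totals()
        np.testing.assert_allclose(
            totals[totals > 0], 10_000, rtol=1e-6
        )
        assert totals[3] == 0

    def test_cell_already_at_target_unchanged(self):
        dense = np.full((1, 4), 2500.0)
        scaled = st.normalize_total(matrix_from_dense(dense))
        np.testing.assert_array_equal(scaled.counts.toarray(), dense)

    def test_double_scaling_rejected(self):
        scaled = st.normalize_total(matrix_from_dense(np.ones((2, 4))))
        with pytest.raises(PipelineError):
            st.normalize_total(scaled)

    def test_log1p_values_and_double_application(self):
        dense = np.array([[0.0, np.e - 1, 0, 0]])
        logged = st.log1p_transform(matrix_from_dense(dense))
        assert logged.counts[0, 1] == pytest.approx(1.0)
        assert logged.counts[0, 0] == 0
        with pytest.raises(PipelineError):
            st.log1p_transform(logged)


class TestFrip:
    peaks = [Peak("chr1", 1000, 2000, "p1", 1000),
             Peak("chr1", 5000, 6000, "p2", 1000)]

    def test_8_of_10_fragments(self):
        frags = [Fragment("chr1", 1100 + i, 1160 + i, "c1") for i in range(8)]
        frags += [Fragment("chr1", 9000, 9060, "c1"),
                  Fragment("chr1", 9500, 9560, "c1")]
        per_cell, pooled = st.frip(frags, self.peaks)
        assert pooled == pytest.approx(0.8)
        assert per_cell["c1"] == pytest.approx(0.8)

    def test_no_peaks_gives_zero(self):
        frags = [Fragment("chr1", 100, 160, "c1")]
        _, pooled = st.frip(frags, [])
        assert pooled == 0.0

    def test_all_in_one_peak_gives_one(self):
        frags = [Fragment("chr1", 1100, 1160, "c1") for _ in range(5)]
        _, pooled = st.frip(frags, self.peaks)
        assert pooled == 1.0

    def test_fragment_counted_once_despite_two_peaks(self):
        peaks = [Peak("chr1", 100, 200, "p1", 1), Peak("chr1", 150, 300, "p2", 1)]
        frags = [Fragment("chr1", 140, 260, "c1")]
        _, pooled = st.frip(frags, peaks)
        assert pooled == 1.0

    def test_zero_reads_error(self):
        with pytest.raises(PipelineError):
            st.frip([], self.peaks)

    def test_bounds_and_monotonicity_under_fuzzing(self, rng):
        frags = [
            Fragment("chr1", int(s), int(s) + 60, f"c{i % 3}")
            for i, s in enumerate(rng.integers(0, 10_000, 60))
        ]
        prev = 0.0
        for k in range(len(self.peaks) + 1):
            _, pooled = st.frip(frags, self.peaks[:k]) if k else (None, 0.0)
            assert 0.0 <= pooled <= 1.0
            assert pooled >= prev
            prev = pooled


class TestQCReport:
    def test_report_consistent_with_matrix(self, small_sim):
        peaks = st.filter_peaks(small_sim.peaks)
        ws = st.make_windows(peaks, chrom_sizes=small_sim.chrom_sizes)
        mats = st.build_matrix(small_sim.all_fragments(), ws, small_sim.design)
        mat = mats["A"]
        report = st.cell_qc_report(mat, min_reads=50)
        assert (report["total_reads_in_windows"] == mat.cell_totals()).all()
        assert (report["nonzero_peaks"] <= mat.n_peaks).all()
        assert (
            report["passed_read_filter"]
            == (mat.cell_totals() > 50)
        ).all()
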