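import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from hypothesis.extra import numpy as hnp
from scipy import sparse

import sctagdiff as st
from sctagdiff.errors import ConfigurationError, PipelineError
from sctagdiff.stats import LN2

import oracles


def blocks_strategy(max_n=8, max_nb=12, max_val=50):
    shapes = hst.tuples(
        hst.integers(1, max_n), hst.integers(1, max_nb)
    )
    return shapes.flatmap(
        lambda s: hnp.arrays(np.int64, s, elements=hst.integers(0, max_val))
    )


class TestMeanLogSignal:
    @pytest.mark.parametrize(
        "block,expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[0, 0], [2, 2]], 1.0),
            ([[4, 4, 4, 4]], 2.0),
        ],
    )
    def test_known_values(self, block, expected):
        assert st.peak_mean_log_signal(np.array(block)) == pytest.approx(expected)

    def test_all_zero_block_is_undefined(self):
        assert np.isnan(st.peak_mean_log_signal(np.zeros((2, 2))))

    def test_empty_block_rejected(self):
        with pytest.raises(ConfigurationError):
            st.peak_mean_log_signal(np.zeros((0, 0)))


class TestLogVariance:
    def test_constant_rows_have_zero_variance(self):
        assert st.peak_log_variance(np.ones((2, 2))) == 0.0

    def test_hand_evaluated_block(self):
        # rows (0,0) and (2,2): quad sum 8, total 4, n_b 2 -> 1/ln2
        c = np.array([[0, 0], [2, 2]])
        assert st.peak_log_variance(c) == pytest.approx(1 / LN2)
        assert st.peak_log_variance(c) == pytest.approx(1.442695, abs=1e-6)

    def test_zero_total_raises(self):
        with pytest.raises(PipelineError, match="zero_total"):
            st.peak_log_variance(np.zeros((2, 2)))

    def test_matches_quadruple_loop_oracle(self, rng):
        for _ in range(20):
            c = rng.integers(0, 10, size=(4, 3)) + 1
            assert st.peak_log_variance(c) == pytest.approx(
                oracles.quadruple_loop_variance(c), abs=1e-12
            )

    @settings(max_examples=200, derandomize=True)
    @given(blocks_strategy())
    def test_row_sum_identity_against_literal_formula(self, c):
        """The O(n*n_b) row-sum form equals the literal double bin sum."""
        if c.sum() == 0:
            return
        fast = st.peak_log_variance(c)
        naive = oracles.naive_log_variance(c)
        assert fast == pytest.approx(naive, abs=1e-9)
        assert fast >= 0

    def test_delta_mode_is_scale_invariant(self, rng):
        c = rng.poisson(3, (10, 4)).astype(float) + 1
        assert st.peak_log_variance(7 * c, mode="delta") == pytest.approx(
            st.peak_log_variance(c, mode="delta")
        )
        # the printed form scales linearly with a global multiplier
        assert st.peak_log_variance(7 * c) == pytest.approx(
            7 * st.peak_log_variance(c)
        )


class TestZscore:
    def worked_example(self):
        a = st.summarize_peak("p", np.array([[0, 0], [2, 2]]))
        b = st.summarize_peak("p", np.array([[2, 2], [2, 2]]))
        return a, b

    def test_worked_micro_example(self):
        a, b = self.worked_example()
        assert (a.zbar, b.zbar) == (1.0, 2.0)
        assert a.var == pytest.approx(1.442695, abs=1e-6)
        assert b.var == 0.0
        z, status = st.peak_zscore(a, b)
        assert status == "ok"
        assert z == pytest.approx(-0.83255, abs=1e-5)

    def test_identical_blocks_give_zero(self, rng):
        c = rng.poisson(2, (5, 4))
        s = st.summarize_peak("p", c)
        z, _ = st.peak_zscore(s, s)
        assert z == 0.0

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a = st.summarize_peak("p", rng.poisson(2, (5, 4)) + 1)
            b = st.summarize_peak("p", rng.poisson(3, (6, 4)) + 1)
            z_ab, _ = st.peak_zscore(a, b)
            z_ba, _ = st.peak_zscore(b, a)
            assert z_ab == pytest.approx(-z_ba)

    def test_zero_total_status_propagates(self):
        a = st.summarize_peak("p", np.zeros((2, 2)))
        b = st.summarize_peak("p", np.ones((2, 2)))
        assert st.peak_zscore(a, b) == (pytest.approx(np.nan, nan_ok=True),
                                        "zero_total_a")
        assert st.peak_zscore(b, a)[1] == "zero_total_b"

    def test_zero_variance_statuses(self):
        same = st.summarize_peak("p", np.ones((2, 2)))
        other = st.summarize_peak("p", 2 * np.ones((2, 2)))
        z, status = st.peak_zscore(same, same)
        assert (z, status) == (0.0, "zero_variance")
        z, status = st.peak_zscore(same, other)
        assert status == "zero_variance" and np.isnan(z)


class TestPvaluesAndBH:
    def test_two_sided_normal_tail(self):
        assert st.zscore_pvalues(0.0) == pytest.approx(1.0)
        assert st.zscore_pvalues(1.959964) == pytest.approx(0.05, abs=1e-6)
        assert st.zscore_pvalues(-1.959964) == st.zscore_pvalues(1.959964)

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            st.bh_adjust([0.01, 0.03, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_bh_trivial_cases(self):
        np.testing.assert_allclose(st.bh_adjust([1.0]), [1.0])
        np.testing.assert_allclose(st.bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
        assert st.bh_adjust([]).size == 0

    @settings(max_examples=100, derandomize=True)
    @given(
        hst.lists(
            hst.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=40
        )
    )
    def test_bh_dominates_p_and_is_permutation_equivariant(self, pvals):
        p = np.array(pvals)
        padj = st.bh_adjust(p)
        assert (padj >= p - 1e-15).all() and (padj <= 1.0 + 1e-15).all()
        perm = np.random.default_rng(1).permutation(len(p))
        np.testing.assert_allclose(st.bh_adjust(p[perm]), padj[perm])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ConfigurationError):
            st.bh_adjust([0.0, 0.5])


class TestRunDifferential:
    def dense_matrices(self, rng, n_peaks=6, n_bins=4, n_cells=8, shift=None):
        def make(seed_shift=0.0):
            dense = rng.poisson(3 + seed_shift, (n_cells, n_peaks * n_bins))
            return st.BinnedCountMatrix(
                counts=sparse.csr_matrix(dense.astype(float)),
                cell_ids=[f"c{seed_shift}_{i}" for i in range(n_cells)],
                peak_ids=[f"p{i}" for i in range(n_peaks)],
                n_bins=n_bins,
            )
        return make(), make(shift if shift is not None else 0.0)

    def test_identical_matrices_select_nothing(self, rng):
        a, _ = self.dense_matrices(rng)
        res = st.run_differential(a, a)
        assert np.allclose(res["z"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)
        assert not res["selected"].any()

    def test_single_peak_table_matches_micro_example(self):
        a = st.BinnedCountMatrix(
            sparse.csr_matrix(np.array([[0.0, 0], [2, 2]])),
            ["c1", "c2"], ["p1"], n_bins=2,
        )
        b = st.BinnedCountMatrix(
            sparse.csr_matrix(np.array([[2.0, 2], [2, 2]])),
            ["d1", "d2"], ["p1"], n_bins=2,
        )
        res = st.run_differential(a, b)
        assert len(res) == 1
        assert res["z"].iloc[0] == pytest.approx(-0.83255, abs=1e-5)

    def test_matches_naive_peak_by_peak_oracle(self, rng):
        a, b = self.dense_matrices(rng, shift=1.0)
        res = st.run_differential(a, b)
        naive = oracles.naive_differential(a, b)
        np.testing.assert_allclose(res["z"], naive["z"], atol=1e-10)
        np.testing.assert_allclose(res["padj"], naive["padj"], atol=1e-10)

    def test_zero_total_peak_excluded_from_bh_family(self, rng):
        a, b = self.dense_matrices(rng)
        dense_a = a.counts.toarray()
        dense_a[:, :a.n_bins] = 0  # peak p0 empty in condition A
        a = st.BinnedCountMatrix(
            sparse.csr_matrix(dense_a), a.cell_ids, a.peak_ids, a.n_bins
        )
        res = st.run_differential(a, b).set_index("peak")
        assert res.loc["p0", "status"] == "zero_total_a"
        assert np.isnan(res.loc["p0", "padj"])
        assert not res.loc["p0", "selected"]
        ok = res[res["status"] == "ok"]
        np.testing.assert_allclose(
            ok["padj"], st.bh_adjust(ok["pvalue"]), atol=1e-12
        )

    def test_column_mismatch_rejected(self, rng):
        a, b = self.dense_matrices(rng)
        with pytest.raises(ConfigurationError):
            st.run_differential(a, b.subset_peaks(list(b.peak_ids[:-1])))

    def test_direction_convention(self, rng):
        # condition A uniformly deeper -> z positive
        base = rng.poisson(3, (8, 12)).astype(float) + 1
        a = st.BinnedCountMatrix(sparse.csr_matrix(base * 4),
                                 [f"a{i}" for i in range(8)], ["p0"], 12)
        b = st.BinnedCountMatrix(sparse.csr_matrix(base),
                                 [f"b{i}" for i in range(8)], ["p0"], 12)
        assert st.run_differential(a, b)["z"].iloc[0] > 0
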