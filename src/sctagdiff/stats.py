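"""Per-peak differential-occupancy z-statistic, p-values, BH selection.

For one peak with an ``n x n_b`` count block ``c`` (cells by bins), the
log-signal is

    zbar = log2( (1 / n_b) * sum_ij c_ij )

and its variance estimate carries the full bin-bin covariance of the
per-cell profiles,

    sigma2 = (1 / (ln 2 * n_b)) * sum_{k,l} sum_m (c_mk - mu_k)(c_ml - mu_l)
                                  / sum_ij c_ij,

with mu_j the per-bin cell average.  The double bin sum collapses
algebraically to ``sum_m (r_m - rbar)^2`` over the per-cell row sums r_m,
which is how it is computed here (O(n * n_b) instead of O(n * n_b^2)); a
test certifies the identity against the literal quadruple sum.  The
two-condition statistic is

    z = (zbar_A - zbar_B) / sqrt(sigma2_A + sigma2_B),

positive when occupancy is higher in the first condition.  Two-sided normal
p-values are adjusted across peaks by Benjamini-Hochberg, and peaks with
adjusted p below ``alpha`` (default 0.001) are selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, PipelineError
from .matrix import BinnedCountMatrix

LN2 = np.log(2.0)

STATUS_OK = "ok"
STATUS_ZERO_TOTAL_A = "zero_total_a"
STATUS_ZERO_TOTAL_B = "zero_total_b"
STATUS_ZERO_VARIANCE = "zero_variance"


@dataclass
class PeakConditionSummary:
    """One peak's per-condition summary statistics."""

    peak: str
    zbar: float          # log2 bin-averaged cell-summed signal (NaN if total 0)
    var: float           # variance estimate of zbar (NaN if total 0)
    bin_means: np.ndarray
    total: float
    n_cells: int


def peak_mean_log_signal(c: np.ndarray) -> float:
    """log2 of the bin-averaged, cell-summed counts of one peak block.

    Returns NaN (the undefined marker) when the block total is zero.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.size == 0:
        raise ConfigurationError("count block must be a non-empty 2-D array")
    total = c.sum()
    if total == 0:
        return np.nan
    return float(np.log2(total / c.shape[1]))


def peak_log_variance(c: np.ndarray, mode: str = "printed") -> float:
    """Variance estimate of the peak's log signal.

    ``printed`` (default) is the form stated above.  ``delta`` is the
    textbook first-order delta-method variance of log2 of a sum of n
    independent cell totals: ``n * s_r^2 / (ln2 * total)^2`` with ``s_r^2``
    the sample variance of the per-cell row sums.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.size == 0:
        raise ConfigurationError("count block must be a non-empty 2-D array")
    total = c.sum()
    if total == 0:
        raise PipelineError("variance undefined for an all-zero block (zero_total)")
    n, n_b = c.shape
    r = c.sum(axis=1)
    ss = float(((r - r.mean()) ** 2).sum())  # == the double bin sum
    if mode == "printed":
        return ss / (LN2 * n_b * total)
    if mode == "delta":
        if n < 2:
            return np.nan
        s2 = ss / (n - 1)
        return n * s2 / (LN2 * total) ** 2
    raise ConfigurationError(f"unknown variance mode {mode!r}")


def summarize_peak(
    peak: str, c: np.ndarray, variance_mode: str = "printed"
) -> PeakConditionSummary:
    c = np.asarray(c, dtype=float)
    total = float(c.sum())
    return PeakConditionSummary(
        peak=peak,
        zbar=peak_mean_log_signal(c),
        var=(
            peak_log_variance(c, mode=variance_mode) if total > 0 else np.nan
        ),
        bin_means=c.mean(axis=0),
        total=total,
        n_cells=c.shape[0],
    )


def peak_zscore(
    summary_a: PeakConditionSummary, summary_b: PeakConditionSummary
) -> tuple[float, str]:
    """z and status for one peak; z > 0 means higher occupancy in A."""
    if summary_a.total == 0:
        return np.nan, STATUS_ZERO_TOTAL_A
    if summary_b.total == 0:
        return np.nan, STATUS_ZERO_TOTAL_B
    denom = summary_a.var + summary_b.var
    if denom == 0:
        if summary_a.zbar == summary_b.zbar:
            return 0.0, STATUS_ZERO_VARIANCE
        return np.nan, STATUS_ZERO_VARIANCE
    return float((summary_a.zbar - summary_b.zbar) / np.sqrt(denom)), STATUS_OK


def zscore_pvalues(z) -> np.ndarray | float:
    """Two-sided standard-normal tail probability, 2 * (1 - Phi(|z|))."""
    z = np.asarray(z, dtype=float)
    p = np.where(np.isnan(z), np.nan, 2.0 * sps.norm.sf(np.abs(z)))
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _condition_summaries(matrix: BinnedCountMatrix, variance_mode: str):
    """Vectorised per-peak (zbar, var, total) for one condition."""
    r = matrix.peak_cell_sums()            # cells x peaks
    total = r.sum(axis=0)
    ss = ((r - r.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zbar = np.where(total > 0, np.log2(total / matrix.n_bins), np.nan)
        if variance_mode == "printed":
            var = np.where(total > 0, ss / (LN2 * matrix.n_bins * total), np.nan)
        elif variance_mode == "delta":
            n = matrix.n_cells
            s2 = ss / max(n - 1, 1)
            var = np.where(total > 0, n * s2 / (LN2 * total) ** 2, np.nan)
        else:
            raise ConfigurationError(f"unknown variance mode {variance_mode!r}")
    return zbar, var, total


def run_differential(
    matrix_a: BinnedCountMatrix,
    matrix_b: BinnedCountMatrix,
    alpha: float = 0.001,
    variance_mode: str = "printed",
) -> pd.DataFrame:
    """Per-peak differential test between two conditions.

    Both matrices must share the peak/bin column layout and scaling state.
    Peaks with zero total in either condition, or with zero pooled variance,
    carry an explanatory status and are excluded from the BH family;
    ``selected`` is ``padj < alpha`` among status-ok peaks.
    """
    if not matrix_a.peak_ids.equals(matrix_b.peak_ids) or (
        matrix_a.n_bins != matrix_b.n_bins
    ):
        raise ConfigurationError("matrices must share peak ids and bin layout")
    if matrix_a.scaled != matrix_b.scaled:
        raise ConfigurationError("matrices must be scaled consistently")

    zbar_a, var_a, total_a = _condition_summaries(matrix_a, variance_mode)
    zbar_b, var_b, total_b = _condition_summaries(matrix_b, variance_mode)

    n_peaks = matrix_a.n_peaks
    status = np.full(n_peaks, STATUS_OK, dtype=object)
    status[total_b == 0] = STATUS_ZERO_TOTAL_B
    status[total_a == 0] = STATUS_ZERO_TOTAL_A
    both = (total_a > 0) & (total_b > 0)
    zero_var = both & (var_a + var_b == 0)
    status[zero_var] = STATUS_ZERO_VARIANCE

    z = np.full(n_peaks, np.nan)
    ok = status == STATUS_OK
    with np.errstate(divide="ignore", invalid="ignore"):
        z[ok] = (zbar_a[ok] - zbar_b[ok]) / np.sqrt(var_a[ok] + var_b[ok])
    z[zero_var & (zbar_a == zbar_b)] = 0.0

    pvalue = np.full(n_peaks, np.nan)
    pvalue[~np.isnan(z)] = zscore_pvalues(z[~np.isnan(z)])

    padj = np.full(n_peaks, np.nan)
    if ok.any():
        padj[ok] = bh_adjust(pvalue[ok])
    selected = ok & (padj < alpha)

    return pd.DataFrame(
        {
            "peak": matrix_a.peak_ids,
            "zbar_a": zbar_a,
            "zbar_b": zbar_b,
            "var_a": var_a,
            "var_b": var_b,
            "z": z,
            "pvalue": pvalue,
            "padj": padj,
            "selected": selected,
            "status": status,
        }
    )


__all__ = [
    "PeakConditionSummary",
    "peak_mean_log_signal",
    "peak_log_variance",
    "summarize_peak",
    "peak_zscore",
    "zscore_pvalues",
    "bh_adjust",
    "run_differential",
]
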