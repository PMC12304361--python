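"""Per-condition count-matrix construction, cell QC filters, scaling, FRiP.

The testing branch of the pipeline is: filter peaks by score, build windows,
build per-condition matrices, keep cells with more than ``min_reads`` reads
in windows, scale each cell to a common total, then test.  The quantile
filter on non-zero peaks and the log(x + 1) transform belong to the
QC/embedding branch only and are never applied before testing.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigurationError, PipelineError
from .io import Fragment, Peak
from .matrix import BinnedCountMatrix
from .windows import PeakWindowSet, assign_fragment


def _fragments_frame(fragments) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        df = fragments.copy()
        if "count" not in df.columns:
            df["count"] = 1
        return df
    frags = list(fragments)
    return pd.DataFrame(
        {
            "chrom": [f.chrom for f in frags],
            "start": [f.start for f in frags],
            "end": [f.end for f in frags],
            "barcode": [f.barcode for f in frags],
            "count": [f.count for f in frags],
        },
        columns=["chrom", "start", "end", "barcode", "count"],
    )


def _windows_disjoint(windows: PeakWindowSet) -> bool:
    t = windows.table.sort_values(["chrom", "start"])
    same = t["chrom"].to_numpy()[1:] == t["chrom"].to_numpy()[:-1]
    return not (same & (t["start"].to_numpy()[1:] < t["end"].to_numpy()[:-1])).any()


def _assign_midpoint_vectorised(
    df: pd.DataFrame, windows: PeakWindowSet
) -> pd.DataFrame:
    """(row index, peak index, bin) for disjoint windows via binary search."""
    table = windows.table
    out = []
    mids = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    for chrom, sub in table.groupby("chrom", sort=False):
        sel = np.flatnonzero(df["chrom"].to_numpy() == chrom)
        if sel.size == 0:
            continue
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        widx = sub.index.to_numpy()[order]
        m = mids[sel]
        j = np.searchsorted(starts, m, side="right") - 1
        ok = (j >= 0) & (m < ends[np.clip(j, 0, None)])
        sel, j, m = sel[ok], j[ok], m[ok]
        out.append(
            pd.DataFrame(
                {
                    "frag": sel,
                    "window": widx[j],
                    "bin": (m - starts[j]) // windows.bin_width,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["frag", "window", "bin"])
    return pd.concat(out, ignore_index=True)


def build_matrix(
    fragments: Iterable[Fragment] | pd.DataFrame,
    windows: PeakWindowSet,
    design: pd.DataFrame,
    mode: str = "midpoint",
) -> dict[str, BinnedCountMatrix]:
    """Accumulate fragment weights into one cells x (peak, bin) matrix per condition.

    Fragments whose barcode is absent from the design are dropped (their
    number is reported with a warning).  Cells with no fragment in any window
    appear as all-zero rows, so both matrices share the design's cell sets
    and an identical column ordering.
    """
    if design["barcode"].duplicated().any():
        raise ConfigurationError("design barcodes must be unique")
    conditions = list(pd.unique(design["condition"]))
    if any((design["condition"] == c).sum() == 0 for c in conditions) or not conditions:
        raise ConfigurationError("every condition needs at least one cell")

    df = _fragments_frame(fragments)
    barcode_pos = pd.Series(
        np.arange(len(design)), index=design["barcode"].to_numpy()
    )
    known = df["barcode"].isin(barcode_pos.index).to_numpy()
    n_unknown = int((~known).sum())
    if n_unknown:
        warnings.warn(
            f"dropped {n_unknown} fragment(s) with barcodes absent from the design"
        )
    df = df.loc[known].reset_index(drop=True)

    peak_ids = windows.peak_ids
    n_bins = windows.n_bins
    window_pos = pd.Series(np.arange(len(windows)), index=windows.table.index)

    if mode == "midpoint" and _windows_disjoint(windows):
        hits = _assign_midpoint_vectorised(df, windows)
        rows = barcode_pos[df["barcode"].to_numpy()[hits["frag"]]].to_numpy()
        cols = (
            window_pos[hits["window"]].to_numpy() * n_bins + hits["bin"].to_numpy()
        )
        weights = df["count"].to_numpy()[hits["frag"]]
    else:
        rows_l, cols_l, weights_l = [], [], []
        for rec in df.itertuples(index=False):
            frag = Fragment(rec.chrom, rec.start, rec.end, rec.barcode, rec.count)
            for peak, b, w in assign_fragment(frag, windows, mode=mode):
                rows_l.append(barcode_pos[rec.barcode])
                cols_l.append(peak_ids.get_loc(peak) * n_bins + b)
                weights_l.append(w)
        rows = np.asarray(rows_l, dtype=int)
        cols = np.asarray(cols_l, dtype=int)
        weights = np.asarray(weights_l, dtype=float)

    full = sparse.csr_matrix(
        (np.asarray(weights, dtype=float), (rows, cols)),
        shape=(len(design), len(peak_ids) * n_bins),
    )
    out: dict[str, BinnedCountMatrix] = {}
    for cond in conditions:
        mask = (design["condition"] == cond).to_numpy()
        out[cond] = BinnedCountMatrix(
            counts=full[np.flatnonzero(mask)],
            cell_ids=pd.Index(design["barcode"].to_numpy()[mask]),
            peak_ids=peak_ids,
            n_bins=n_bins,
        )
    return out


def cell_qc_report(
    matrix: BinnedCountMatrix,
    min_reads: int = 250,
    lower: float = 0.15,
    upper: float = 0.05,
) -> pd.DataFrame:
    """Per-cell QC summary: in-window totals, non-zero peaks, filter flags."""
    totals = matrix.cell_totals()
    nonzero = matrix.nonzero_peaks_per_cell()
    lo, hi = _quantile_bounds(nonzero, lower, upper)
    return pd.DataFrame(
        {
            "barcode": matrix.cell_ids,
            "total_reads_in_windows": totals,
            "nonzero_peaks": nonzero,
            "passed_read_filter": totals > min_reads,
            "passed_quantile_filter": (nonzero >= lo) & (nonzero <= hi),
        }
    )


def filter_cells_by_reads(
    matrix: BinnedCountMatrix, min_reads: int = 250
) -> BinnedCountMatrix:
    """Keep cells with strictly more than ``min_reads`` reads in peak windows."""
    if matrix.scaled:
        raise PipelineError("read filtering must precede scaling")
    keep = matrix.cell_totals() > min_reads
    if not keep.any():
        raise PipelineError(
            f"no cells with more than {min_reads} reads in windows; "
            "review the threshold or the input depth"
        )
    return matrix.subset_cells(keep)


def _quantile_bounds(values: np.ndarray, lower: float, upper: float):
    if lower + upper >= 1:
        raise ConfigurationError(
            f"lower ({lower}) + upper ({upper}) quantile fractions must be < 1"
        )
    if lower < 0 or upper < 0:
        raise ConfigurationError("quantile fractions must be >= 0")
    lo = np.quantile(values, lower, method="linear")
    hi = np.quantile(values, 1 - upper, method="linear")
    return lo, hi


def quantile_filter_cells(
    matrix: BinnedCountMatrix, lower: float = 0.15, upper: float = 0.05
) -> BinnedCountMatrix:
    """Drop cells in the extreme tails of the non-zero-peak distribution.

    Cells whose number of non-zero peaks falls strictly below the ``lower``
    quantile or strictly above the ``1 - upper`` quantile (linear
    interpolation) are removed; boundary cells are kept.  Defaults remove
    the lower 15% and upper 5% tails.  Note the thresholds are taken from
    the distribution at call time, so re-application trims further.
    """
    nonzero = matrix.nonzero_peaks_per_cell()
    lo, hi = _quantile_bounds(nonzero, lower, upper)
    return matrix.subset_cells((nonzero >= lo) & (nonzero <= hi))


def normalize_total(
    matrix: BinnedCountMatrix, target: float = 10_000
) -> BinnedCountMatrix:
    """Scale every non-empty cell's counts so its row total equals ``target``.

    All-zero cells are left at zero with a warning.  Double scaling is an
    error.
    """
    if target <= 0:
        raise ConfigurationError(f"scale target must be > 0, got {target}")
    if matrix.scaled:
        raise PipelineError("matrix is already scaled")
    totals = matrix.cell_totals()
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} all-zero cell(s) left unscaled")
    factors = np.divide(
        target, totals, out=np.zeros_like(totals, dtype=float), where=~empty
    )
    scaled = sparse.diags(factors) @ matrix.counts
    return BinnedCountMatrix(
        counts=sparse.csr_matrix(scaled),
        cell_ids=matrix.cell_ids,
        peak_ids=matrix.peak_ids,
        n_bins=matrix.n_bins,
        scaled=True,
        log_transformed=matrix.log_transformed,
    )


def log1p_transform(matrix: BinnedCountMatrix) -> BinnedCountMatrix:
    """Elementwise natural log(x + 1); QC/embedding branch only."""
    if matrix.log_transformed:
        raise PipelineError("matrix is already log-transformed")
    return BinnedCountMatrix(
        counts=matrix.counts.log1p(),
        cell_ids=matrix.cell_ids,
        peak_ids=matrix.peak_ids,
        n_bins=matrix.n_bins,
        scaled=matrix.scaled,
        log_transformed=True,
    )


def frip(
    fragments: Iterable[Fragment] | pd.DataFrame, peaks: list[Peak]
) -> tuple[pd.Series, float]:
    """Fraction of reads in peaks, per cell and pooled.

    A fragment counts as "in peaks" once if it overlaps at least one peak,
    regardless of how many peaks it hits.  Returns ``(per_cell, pooled)``
    fractions in [0, 1].  Zero total reads is an error; an empty peak set
    gives 0 everywhere.
    """
    df = _fragments_frame(fragments)
    total_per_cell = df.groupby("barcode", sort=True)["count"].sum()
    if df["count"].sum() == 0 or df.empty:
        raise PipelineError("FRiP undefined for zero total reads")

    # merged peak intervals per chromosome for single-hit overlap queries
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))

    in_peak = np.zeros(len(df), dtype=bool)
    for chrom, (starts, ends) in merged.items():
        sel = np.flatnonzero(df["chrom"].to_numpy() == chrom)
        if sel.size == 0:
            continue
        s = df["start"].to_numpy()[sel]
        e = df["end"].to_numpy()[sel]
        j = np.searchsorted(starts, e, side="left") - 1
        hit = (j >= 0) & (ends[np.clip(j, 0, None)] > s)
        in_peak[sel] = hit

    hits_per_cell = (
        df.loc[in_peak].groupby("barcode", sort=True)["count"].sum()
        .reindex(total_per_cell.index, fill_value=0)
    )
    per_cell = hits_per_cell / total_per_cell
    pooled = float(df.loc[in_peak, "count"].sum() / df["count"].sum())
    return per_cell, pooled


__all__ = [
    "build_matrix",
    "cell_qc_report",
    "filter_cells_by_reads",
    "quantile_filter_cells",
    "normalize_total",
    "log1p_transform",
    "frip",
]
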