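"""Cells-by-(peak, bin) sparse count matrix container.

The matrix holds, for one condition, the per-cell fragment counts in each of
the ``n_bins`` fixed-width bins of every retained peak window.  Columns are
ordered peak-major: column ``p * n_bins + j`` is bin ``j`` of peak ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigurationError


@dataclass
class BinnedCountMatrix:
    """Sparse non-negative cells x (peaks * n_bins) count matrix.

    Attributes
    ----------
    counts:
        CSR matrix of shape ``(n_cells, n_peaks * n_bins)``.
    cell_ids:
        Cell barcodes (row labels), unique.
    peak_ids:
        Peak identifiers (column-block labels), unique.
    n_bins:
        Number of bins per peak window (identical for every peak).
    scaled:
        Whether per-cell totals have been scaled to a common target.
    log_transformed:
        Whether a log(x + 1) transform has been applied.
    """

    counts: sparse.csr_matrix
    cell_ids: pd.Index
    peak_ids: pd.Index
    n_bins: int
    scaled: bool = False
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.cell_ids = pd.Index(self.cell_ids)
        self.peak_ids = pd.Index(self.peak_ids)
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        if not self.cell_ids.is_unique:
            raise ConfigurationError("cell barcodes must be unique")
        if not self.peak_ids.is_unique:
            raise ConfigurationError("peak ids must be unique")
        n_cells, n_cols = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ConfigurationError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_cols != len(self.peak_ids) * self.n_bins:
            raise ConfigurationError(
                f"matrix has {n_cols} columns, expected "
                f"{len(self.peak_ids)} peaks x {self.n_bins} bins"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ConfigurationError("counts must be non-negative")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    # -- derived per-cell / per-peak summaries ---------------------------
    def cell_totals(self) -> np.ndarray:
        """Total counts per cell across all peak bins."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def peak_cell_sums(self) -> np.ndarray:
        """Dense ``(n_cells, n_peaks)`` array of per-peak row sums.

        Row m, column p holds cell m's summed counts over the bins of peak p
        (the quantity the variance of the log signal reduces to).
        """
        pooling = sparse.csr_matrix(
            (
                np.ones(self.n_peaks * self.n_bins),
                np.repeat(np.arange(self.n_peaks), self.n_bins),
                np.arange(self.n_peaks * self.n_bins + 1),
            ),
            shape=(self.n_peaks * self.n_bins, self.n_peaks),
        )
        return np.asarray((self.counts @ pooling).todense())

    def nonzero_peaks_per_cell(self) -> np.ndarray:
        """Number of peaks with at least one count, per cell."""
        return (self.peak_cell_sums() > 0).sum(axis=1)

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, keep: np.ndarray) -> "BinnedCountMatrix":
        """Row subset by boolean mask or integer positions (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self, counts=self.counts[keep], cell_ids=self.cell_ids[keep]
        )

    def subset_peaks(self, peak_ids) -> "BinnedCountMatrix":
        """Column-block subset to the given peak ids (in the given order)."""
        idx = self.peak_ids.get_indexer(pd.Index(peak_ids))
        if (idx < 0).any():
            missing = [p for p, i in zip(peak_ids, idx) if i < 0]
            raise KeyError(f"unknown peak ids: {missing[:5]}")
        cols = (idx[:, None] * self.n_bins + np.arange(self.n_bins)).ravel()
        return replace(
            self,
            counts=sparse.csr_matrix(self.counts[:, cols]),
            peak_ids=pd.Index(peak_ids),
        )

    def peak_block(self, peak_id) -> np.ndarray:
        """Dense ``(n_cells, n_bins)`` count block of one peak."""
        p = self.peak_ids.get_loc(peak_id)
        cols = slice(p * self.n_bins, (p + 1) * self.n_bins)
        return np.asarray(self.counts[:, cols].todense())


__all__ = ["BinnedCountMatrix"]
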