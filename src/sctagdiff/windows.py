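"""Peak score filtering, fixed-bin analysis windows, fragment-to-bin assignment.

Each retained peak contributes one window of ``2 * flank`` bp centred on the
peak-interval midpoint, divided into ``(2 * flank) / bin_width`` contiguous
bins.  Every window has the same bin count, which the downstream variance
formula requires; peaks whose window would run off the chromosome are dropped
rather than clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError
from .io import Fragment, Peak


def filter_peaks(peaks: list[Peak], min_score: float = 1000) -> list[Peak]:
    """Retain peaks whose score is >= ``min_score`` (order preserved).

    The default keeps only maximal-confidence peak calls (narrowPeak column 5
    at or above 1000).
    """
    kept = [p for p in peaks if p.score >= min_score]
    if peaks and not kept:
        warnings.warn(f"no peaks passed the score >= {min_score} filter")
    return kept


@dataclass
class PeakWindowSet:
    """Binned analysis windows for a set of peaks.

    ``table`` has one row per retained peak: peak, chrom, start, end
    (window bounds, half-open).  ``dropped`` lists peaks whose window would
    cross a chromosome boundary.
    """

    table: pd.DataFrame
    n_bins: int
    bin_width: int
    flank: int
    dropped: list[str] = field(default_factory=list)
    _trees: dict[str, IntervalTree] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.n_bins * self.bin_width != 2 * self.flank:
            raise ConfigurationError(
                f"n_bins ({self.n_bins}) x bin_width ({self.bin_width}) "
                f"must equal the window length {2 * self.flank}"
            )

    @property
    def peak_ids(self) -> pd.Index:
        return pd.Index(self.table["peak"])

    def __len__(self) -> int:
        return len(self.table)

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for i, row in enumerate(self.table.itertuples(index=False)):
                trees.setdefault(row.chrom, IntervalTree()).addi(
                    row.start, row.end, i
                )
            self._trees = trees
        return self._trees


def make_windows(
    peaks: list[Peak],
    flank: int = 2500,
    bin_width: int = 50,
    chrom_sizes: dict[str, int] | None = None,
) -> PeakWindowSet:
    """Build ``[centre - flank, centre + flank)`` windows with fixed-width bins.

    The centre is the floor of the peak-interval midpoint.  With the defaults
    (flank 2500 bp, 50-bp bins) every window has exactly 100 bins.  Peaks
    whose window would start before base 0, or run past the chromosome end
    when ``chrom_sizes`` is given, are dropped and reported.
    """
    if (2 * flank) % bin_width != 0:
        raise ConfigurationError(
            f"bin_width {bin_width} does not divide window length {2 * flank}"
        )
    n_bins = (2 * flank) // bin_width
    rows, dropped = [], []
    for p in peaks:
        centre = (p.start + p.end) // 2
        start, end = centre - flank, centre + flank
        if start < 0 or (
            chrom_sizes is not None and end > chrom_sizes.get(p.chrom, end)
        ):
            dropped.append(p.name)
            continue
        rows.append({"peak": p.name, "chrom": p.chrom, "start": start, "end": end})
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} peak(s) with out-of-bounds windows: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    table = pd.DataFrame(rows, columns=["peak", "chrom", "start", "end"])
    return PeakWindowSet(
        table=table, n_bins=n_bins, bin_width=bin_width, flank=flank,
        dropped=dropped,
    )


def assign_fragment(
    fragment: Fragment,
    windows: PeakWindowSet,
    mode: str = "midpoint",
) -> list[tuple[str, int, int]]:
    """Locate a fragment in the peak windows.

    midpoint mode (default): the fragment midpoint is placed in exactly one
    bin of every window containing it; weight = fragment count.  This
    conserves totals.

    overlap mode: one entry per bin the fragment interval intersects, each
    with weight = fragment count, emulating per-bin read-overlap coverage
    counting (a straddling fragment is multi-counted).

    Fragments outside all windows yield an empty list.  Overlapping windows
    each receive the fragment independently.
    """
    if mode not in ("midpoint", "overlap"):
        raise ConfigurationError(f"unknown assignment mode {mode!r}")
    trees = windows._index()
    tree = trees.get(fragment.chrom)
    if tree is None:
        return []
    table = windows.table
    out: list[tuple[str, int, int]] = []
    if mode == "midpoint":
        mid = fragment.midpoint
        for iv in tree.at(mid):
            i = iv.data
            w_start = int(table["start"].iat[i])
            out.append(
                (
                    table["peak"].iat[i],
                    (mid - w_start) // windows.bin_width,
                    fragment.count,
                )
            )
    else:
        for iv in tree.overlap(fragment.start, fragment.end):
            i = iv.data
            w_start = int(table["start"].iat[i])
            w_end = int(table["end"].iat[i])
            lo = max(fragment.start, w_start)
            hi = min(fragment.end, w_end)  # > lo by construction
            first = (lo - w_start) // windows.bin_width
            last = (hi - 1 - w_start) // windows.bin_width
            peak = table["peak"].iat[i]
            out.extend((peak, b, fragment.count) for b in range(first, last + 1))
    return out


__all__ = ["filter_peaks", "make_windows", "assign_fragment", "PeakWindowSet"]
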