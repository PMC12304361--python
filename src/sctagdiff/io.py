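"""Readers and writers for the on-disk formats used throughout the pipeline.

All genomic coordinates are 0-based half-open (BED convention).  Every reader
accepts plain-text or gzip-compressed input, sniffed by the ``.gz`` extension.
Unknown trailing columns are ignored with a warning rather than an error.
"""

from __future__ import annotations

import gzip
import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import FormatError, ParseError
from .matrix import BinnedCountMatrix


@dataclass(frozen=True)
class Peak:
    """One called peak interval (narrowPeak columns 1-5)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"peak {self.name}: start {self.start} < 0")
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.name}: end {self.end} <= start {self.start}"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.name}: score {self.score} < 0")


@dataclass(frozen=True)
class Fragment:
    """One sequenced tagmentation fragment attributed to a cell barcode."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end {self.end} <= start {self.start}")
        if self.count < 1:
            raise ValueError(f"fragment count {self.count} < 1")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime so identical content yields identical bytes
            return io.TextIOWrapper(gzip.GzipFile(path, mode="wb", mtime=0))
        return gzip.open(path, mode)
    return open(path, mode)


def _int_field(raw: str, what: str, path, lineno: int) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ParseError(f"non-integer {what} {raw!r}", path, lineno) from None


# ---------------------------------------------------------------------------
# peaks (narrowPeak / BED6+4)
# ---------------------------------------------------------------------------

def read_narrowpeak(path) -> list[Peak]:
    """Read a MACS2 narrowPeak (BED6+4) or BED6 file into a list of peaks.

    Lines must have at least 6 tab-separated columns.  A ``.`` in the name
    column is replaced by an auto-generated unique name.  Malformed
    coordinates raise :class:`ParseError` naming the offending line.
    """
    peaks: list[Peak] = []
    seen: set[str] = set()
    warned_extra = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"expected >= 6 tab-separated columns, got {len(fields)}",
                    path,
                    lineno,
                )
            if len(fields) > 10 and not warned_extra:
                warnings.warn(
                    f"{path}: ignoring columns beyond 10 in narrowPeak input"
                )
                warned_extra = True
            chrom = fields[0]
            start = _int_field(fields[1], "start", path, lineno)
            end = _int_field(fields[2], "end", path, lineno)
            name = fields[3] if fields[3] != "." else f"peak_{lineno}"
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(
                    f"non-numeric score {fields[4]!r}", path, lineno
                ) from None
            try:
                peak = Peak(chrom, start, end, name, score)
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
            if peak.name in seen:
                raise ParseError(f"duplicate peak name {peak.name!r}", path, lineno)
            seen.add(peak.name)
            peaks.append(peak)
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    """Write peaks as 10-column narrowPeak (strand/stat columns as ``.``/-1)."""
    with _open_text(path, "wt") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}"
                "\t.\t-1\t-1\t-1\t-1\n"
            )


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def read_fragments(path) -> Iterator[Fragment]:
    """Stream fragments from a TSV (chrom, start, end, barcode[, count]).

    Yields one :class:`Fragment` at a time without loading the file; a
    missing fifth column means count 1.  A count <= 0 or a non-integer
    coordinate raises :class:`ParseError`.
    """
    warned_extra = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"expected >= 4 tab-separated columns, got {len(fields)}",
                    path,
                    lineno,
                )
            if len(fields) > 5 and not warned_extra:
                warnings.warn(f"{path}: ignoring columns beyond 5 in fragments")
                warned_extra = True
            start = _int_field(fields[1], "start", path, lineno)
            end = _int_field(fields[2], "end", path, lineno)
            count = 1
            if len(fields) >= 5 and fields[4] != "":
                count = _int_field(fields[4], "count", path, lineno)
            try:
                yield Fragment(fields[0], start, end, fields[3], count)
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None


def read_fragments_frame(path) -> pd.DataFrame:
    """Whole-file fragment reader returning a DataFrame.

    Yields the same multiset of records as :func:`read_fragments`; convenient
    for vectorised downstream work.
    """
    frags = list(read_fragments(path))
    return pd.DataFrame(
        {
            "chrom": [f.chrom for f in frags],
            "start": [f.start for f in frags],
            "end": [f.end for f in frags],
            "barcode": [f.barcode for f in frags],
            "count": [f.count for f in frags],
        }
    )


def write_fragments(fragments: Iterable[Fragment], path) -> None:
    with _open_text(path, "wt") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.barcode}\t{f.count}\n")


# ---------------------------------------------------------------------------
# design table (barcode -> condition)
# ---------------------------------------------------------------------------

def read_design(path) -> pd.DataFrame:
    """Read a barcode/condition design TSV (header optional).

    Returns a two-column DataFrame ``barcode, condition`` with unique
    barcodes and at least one cell per condition.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ParseError("design table needs 2 columns (barcode, condition)", path)
    df = df.iloc[:, :2]
    df.columns = ["barcode", "condition"]
    if list(df.iloc[0]) == ["barcode", "condition"]:
        df = df.iloc[1:].reset_index(drop=True)
    if df["barcode"].duplicated().any():
        dup = df["barcode"][df["barcode"].duplicated()].iloc[0]
        raise ParseError(f"duplicate barcode {dup!r} in design table", path)
    if (df.groupby("condition").size() < 1).any() or df.empty:
        raise ParseError("every condition needs at least one cell", path)
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design[["barcode", "condition"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sparse matrix directory (triplets + cells.tsv + features.tsv + meta.json)
# ---------------------------------------------------------------------------

_MATRIX_FILES = ("matrix.tsv", "cells.tsv", "features.tsv", "meta.json")


def write_sparse_matrix(matrix: BinnedCountMatrix, directory) -> None:
    """Write a matrix as triplets plus cell and feature companion tables.

    ``matrix.tsv`` holds one stored entry per line (row, col, value);
    ``cells.tsv`` the row barcodes; ``features.tsv`` the (peak id, bin index)
    of each column.  Round-trip through :func:`read_sparse_matrix` is exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    with open(directory / "matrix.tsv", "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{float(v)!r}\n")
    pd.DataFrame({"barcode": matrix.cell_ids}).to_csv(
        directory / "cells.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "peak": np.repeat(matrix.peak_ids, matrix.n_bins),
            "bin": np.tile(np.arange(matrix.n_bins), matrix.n_peaks),
        }
    ).to_csv(directory / "features.tsv", sep="\t", index=False)
    meta = {
        "n_bins": matrix.n_bins,
        "scaled": matrix.scaled,
        "log_transformed": matrix.log_transformed,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def read_sparse_matrix(directory) -> BinnedCountMatrix:
    directory = Path(directory)
    for name in _MATRIX_FILES:
        if not (directory / name).exists():
            raise FormatError(f"{directory}: missing companion file {name}")
    meta = json.loads((directory / "meta.json").read_text())
    cells = pd.read_csv(directory / "cells.tsv", sep="\t", dtype=str)["barcode"]
    features = pd.read_csv(directory / "features.tsv", sep="\t")
    n_bins = int(meta["n_bins"])
    peak_ids = features["peak"].iloc[::n_bins].reset_index(drop=True)
    trip = pd.read_csv(directory / "matrix.tsv", sep="\t")
    n_rows, n_cols = len(cells), len(features)
    if len(trip):
        if trip["row"].max() >= n_rows or trip["row"].min() < 0:
            raise FormatError(f"{directory}: triplet row index out of range")
        if trip["col"].max() >= n_cols or trip["col"].min() < 0:
            raise FormatError(f"{directory}: triplet column index out of range")
    counts = sparse.csr_matrix(
        (
            trip["value"].to_numpy(dtype=float),
            (trip["row"].to_numpy(dtype=int), trip["col"].to_numpy(dtype=int)),
        ),
        shape=(n_rows, n_cols),
    )
    return BinnedCountMatrix(
        counts=counts,
        cell_ids=pd.Index(cells),
        peak_ids=pd.Index(peak_ids),
        n_bins=n_bins,
        scaled=bool(meta["scaled"]),
        log_transformed=bool(meta["log_transformed"]),
    )


# ---------------------------------------------------------------------------
# gene annotations (BED6) and gene sets (GMT)
# ---------------------------------------------------------------------------

def read_bed6(path) -> pd.DataFrame:
    """Read BED6 records (chrom, start, end, name, score, strand)."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError("BED6 needs >= 6 columns", path, lineno)
            start = _int_field(fields[1], "start", path, lineno)
            end = _int_field(fields[2], "end", path, lineno)
            if end <= start:
                raise ParseError(f"end {end} <= start {start}", path, lineno)
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "name": fields[3],
                    "score": fields[4],
                    "strand": fields[5],
                }
            )
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (set name, description, member genes...)."""
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description, >=1 gene",
                                 path, lineno)
            if fields[0] in sets:
                raise ParseError(f"duplicate gene set {fields[0]!r}", path, lineno)
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "peak", "zbar_a", "zbar_b", "var_a", "var_b",
    "z", "pvalue", "padj", "selected", "status",
]


def write_results(results: pd.DataFrame, path) -> None:
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing result columns {sorted(missing)}")
    return df
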