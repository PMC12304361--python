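"""Synthetic two-condition single-cell tagmentation data with known truth.

The generative model mirrors the structure the differential z-statistic
assumes: independent cells, peak-localised signal correlated across the
bins of a window, and per-cell depth variation.  Per peak ``p`` and
condition ``g`` the intensity is ``lambda_pg = base_p * 2^(lfc_p * [g = B])``
(the effect is applied to the second condition); each cell ``i`` draws a
depth factor ``d_i ~ LogNormal(mu, sigma)``; bin ``j`` carries a weight
``w_j`` from a discretised Gaussian centred mid-window (sum 1); fragment
counts are ``Poisson(d_i * lambda_pg * w_j)`` and each count is
materialised as a fragment of realistic length (uniform 30-120 bp) whose
midpoint lies in bin ``j``.  Background fragments fall uniformly outside
the windows, controlling FRiP.  Everything is driven by one explicit seed;
identical configs produce byte-identical output files.

Peaks live on a single synthetic chromosome ``chrS``, spaced so that their
analysis windows do not overlap (2 x flank + 1 kb between centres).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .errors import ConfigurationError
from .io import Peak

CHROM = "chrS"
_MARGIN = 10_000          # bp clear of the chromosome ends
_GAP = 1_000              # bp between adjacent windows
_PEAK_HALFWIDTH = 250     # called-peak interval half-width


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-condition single-cell simulation.

    Defaults are the package's reference recovery scenario: 500 peaks, 10%
    carrying a |log2FC| of 2 (split evenly between gains and losses in
    condition B), 150 cells per condition, 0.4 expected reads per peak per
    cell before depth scaling (60 reads per peak per condition), unit-mean
    lognormal depth, a 150-bp-sd signal footprint, and enough background
    for a FRiP around 0.7.
    """

    seed: int
    n_peaks: int = 500
    frac_diff: float = 0.10
    effect_log2fc: float = 2.0
    cells_per_condition: int = 150
    depth_lognormal_mu: float = -0.125
    depth_lognormal_sigma: float = 0.5
    mean_peak_reads: float = 0.4       # per peak per cell, pre-depth
    base_intensity_sigma: float = 0.3  # lognormal spread of per-peak baselines
    profile_sigma_bins: float = 3.0
    background_rate: float = 50.0      # fragments per cell outside windows
    flank: int = 2500
    bin_width: int = 50
    frag_len_range: tuple[int, int] = (30, 120)
    nb_dispersion: float | None = None  # gamma shape for negative-binomial bins
    conditions: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if not 0 <= self.frac_diff <= 1:
            raise ConfigurationError("frac_diff must lie in [0, 1]")
        positive = {
            "n_peaks": self.n_peaks,
            "cells_per_condition": self.cells_per_condition,
            "mean_peak_reads": self.mean_peak_reads,
            "flank": self.flank,
            "bin_width": self.bin_width,
            "profile_sigma_bins": self.profile_sigma_bins,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be >= 0")
        if (2 * self.flank) % self.bin_width != 0:
            raise ConfigurationError("bin_width must divide the window length")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ConfigurationError("exactly two distinct conditions required")

    @property
    def n_bins(self) -> int:
        return (2 * self.flank) // self.bin_width


@dataclass
class SimResult:
    """In-memory outputs of one simulated experiment."""

    config: SimConfig
    peaks: list[Peak]
    fragments: dict[str, pd.DataFrame]   # condition -> chrom/start/end/barcode/count
    design: pd.DataFrame
    truth: pd.DataFrame                  # peak, true_log2fc, base_intensity
    chrom_sizes: dict[str, int]
    paths: dict[str, Path] = field(default_factory=dict)

    def all_fragments(self) -> pd.DataFrame:
        return pd.concat(self.fragments.values(), ignore_index=True)


def _geometry(config: SimConfig):
    spacing = 2 * config.flank + _GAP
    centres = _MARGIN + config.flank + np.arange(config.n_peaks) * spacing
    win_start = centres - config.flank
    win_end = centres + config.flank
    chrom_len = int(win_end[-1] + config.flank + _MARGIN)
    return centres, win_start, win_end, chrom_len


def _bin_profile(config: SimConfig) -> np.ndarray:
    centres = np.arange(config.n_bins) + 0.5
    mid = config.n_bins / 2
    w = np.exp(-0.5 * ((centres - mid) / config.profile_sigma_bins) ** 2)
    return w / w.sum()


def _truth_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_eff = round(config.frac_diff * config.n_peaks)
    lfc = np.zeros(config.n_peaks)
    which = rng.choice(config.n_peaks, size=n_eff, replace=False)
    signs = np.where(np.arange(n_eff) % 2 == 0, 1.0, -1.0)
    lfc[np.sort(which)] = signs * config.effect_log2fc
    base = config.mean_peak_reads * rng.lognormal(
        -0.5 * config.base_intensity_sigma**2,
        config.base_intensity_sigma,
        config.n_peaks,
    )
    return pd.DataFrame(
        {
            "peak": [f"peak_{i:05d}" for i in range(config.n_peaks)],
            "true_log2fc": lfc,
            "base_intensity": base,
        }
    )


def _condition_fragments(
    config: SimConfig,
    rng: np.random.Generator,
    lam: np.ndarray,
    barcodes: list[str],
    win_start: np.ndarray,
    win_end: np.ndarray,
    chrom_len: int,
) -> pd.DataFrame:
    n_cells, n_peaks, n_bins = len(barcodes), config.n_peaks, config.n_bins
    lmin, lmax = config.frag_len_range
    depth = rng.lognormal(
        config.depth_lognormal_mu, config.depth_lognormal_sigma, n_cells
    )
    rate = depth[:, None] * lam[None, :]
    if config.nb_dispersion is not None:
        k = config.nb_dispersion
        rate = rate * rng.gamma(k, 1.0 / k, size=rate.shape)
    n_ip = rng.poisson(rate)                       # cells x peaks
    flat = n_ip.ravel()
    idx = np.repeat(np.arange(flat.size), flat)
    cell_i, peak_p = np.unravel_index(idx, (n_cells, n_peaks))

    w = _bin_profile(config)
    bins = rng.choice(n_bins, size=idx.size, p=w)
    mids = (
        win_start[peak_p]
        + bins * config.bin_width
        + rng.integers(0, config.bin_width, idx.size)
    )
    lengths = rng.integers(lmin, lmax + 1, idx.size)
    starts = mids - lengths // 2
    ends = starts + lengths

    # background: midpoints uniform over the complement of the windows
    n_bg_per_cell = rng.poisson(config.background_rate, n_cells)
    n_bg = int(n_bg_per_cell.sum())
    gap_starts = np.concatenate([[0], win_end])
    gap_ends = np.concatenate([win_start, [chrom_len]])
    gap_len = gap_ends - gap_starts
    gap_cum = np.concatenate([[0], np.cumsum(gap_len)])
    u = rng.integers(0, gap_cum[-1], n_bg)
    g = np.searchsorted(gap_cum, u, side="right") - 1
    bg_mid = gap_starts[g] + (u - gap_cum[g])
    bg_len = rng.integers(lmin, lmax + 1, n_bg)
    bg_start = np.maximum(bg_mid - bg_len // 2, 0)
    bg_cell = np.repeat(np.arange(n_cells), n_bg_per_cell)

    frame = pd.DataFrame(
        {
            "chrom": CHROM,
            "start": np.concatenate([starts, bg_start]),
            "end": np.concatenate([ends, bg_start + bg_len]),
            "barcode": np.asarray(barcodes, dtype=object)[
                np.concatenate([cell_i, bg_cell])
            ],
            "count": 1,
        }
    )
    order = rng.permutation(len(frame))
    return frame.iloc[order].reset_index(drop=True)


def simulate_experiment(config: SimConfig, out_dir=None) -> SimResult:
    """Generate fragments, peaks, design and truth for one experiment.

    When ``out_dir`` is given, writes ``fragments_<condition>.tsv.gz``,
    ``peaks.narrowPeak``, ``design.tsv``, ``truth.tsv`` and
    ``provenance.json`` (all re-readable through the package's readers) and
    records the paths in the result.
    """
    rng = np.random.default_rng(config.seed)
    centres, win_start, win_end, chrom_len = _geometry(config)
    truth = _truth_table(config, rng)

    scores = 1000 + rng.integers(0, 1000, config.n_peaks)
    peaks = [
        Peak(
            CHROM,
            int(c - _PEAK_HALFWIDTH),
            int(c + _PEAK_HALFWIDTH),
            name,
            float(s),
        )
        for c, name, s in zip(centres, truth["peak"], scores)
    ]

    cond_a, cond_b = config.conditions
    base = truth["base_intensity"].to_numpy()
    lam = {
        cond_a: base,
        cond_b: base * 2.0 ** truth["true_log2fc"].to_numpy(),
    }
    fragments: dict[str, pd.DataFrame] = {}
    design_rows = []
    for cond in config.conditions:
        barcodes = [
            f"{cond}_{i:04d}" for i in range(config.cells_per_condition)
        ]
        design_rows.extend({"barcode": b, "condition": cond} for b in barcodes)
        fragments[cond] = _condition_fragments(
            config, rng, lam[cond], barcodes, win_start, win_end, chrom_len
        )
    design = pd.DataFrame(design_rows)

    result = SimResult(
        config=config,
        peaks=peaks,
        fragments=fragments,
        design=design,
        truth=truth,
        chrom_sizes={CHROM: chrom_len},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for cond, frame in fragments.items():
            p = out_dir / f"fragments_{cond}.tsv.gz"
            sio.write_fragments(
                (
                    sio.Fragment(r.chrom, r.start, r.end, r.barcode, r.count)
                    for r in frame.itertuples(index=False)
                ),
                p,
            )
            paths[f"fragments_{cond}"] = p
        paths["peaks"] = out_dir / "peaks.narrowPeak"
        sio.write_narrowpeak(peaks, paths["peaks"])
        paths["design"] = out_dir / "design.tsv"
        sio.write_design(design, paths["design"])
        paths["truth"] = out_dir / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["provenance"] = out_dir / "provenance.json"
        prov = dataclasses.asdict(config)
        prov["chrom_sizes"] = {CHROM: chrom_len}
        paths["provenance"].write_text(json.dumps(prov, indent=1, default=list))
        result.paths = paths
    return result


def simulate_null(config: SimConfig, out_dir=None) -> SimResult:
    """Same generator with the differential fraction forced to zero."""
    return simulate_experiment(
        dataclasses.replace(config, frac_diff=0.0), out_dir=out_dir
    )


# ---------------------------------------------------------------------------
# bulk-integration fixture
# ---------------------------------------------------------------------------

@dataclass
class BulkFixture:
    counts_a: pd.Series
    counts_b: pd.Series
    gene_sets: dict[str, list[str]]
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_bulk_fixture(
    n_genes: int = 2000,
    set_size: int = 200,
    n_affected_sets: int = 1,
    n_null_sets: int = 5,
    effect_ratio: float = 2.0,
    n_zero_genes: int = 10,
    base_mean: float = 100.0,
    seed: int = 0,
    out_dir=None,
) -> BulkFixture:
    """Per-gene count tables for two conditions plus gene sets with known truth.

    Genes in "affected" sets have condition-A counts drawn at
    ``effect_ratio`` times their condition-B intensity, so the expected
    mean log2 ratio of an affected set is ``log2(effect_ratio)``.  A few
    genes are deliberately zeroed in one condition to exercise the
    zero-exclusion rule downstream.
    """
    needed = (n_affected_sets + n_null_sets) * set_size
    if needed > n_genes:
        raise ConfigurationError(
            f"{needed} genes needed for the requested sets, have {n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene_{i:05d}" for i in range(n_genes)])
    order = rng.permutation(n_genes)

    gene_sets: dict[str, list[str]] = {}
    affected = np.zeros(n_genes, dtype=bool)
    pos = 0
    for s in range(n_affected_sets):
        idx = order[pos: pos + set_size]
        gene_sets[f"affected_{s + 1}"] = sorted(genes[idx])
        affected[idx] = True
        pos += set_size
    for s in range(n_null_sets):
        idx = order[pos: pos + set_size]
        gene_sets[f"null_{s + 1}"] = sorted(genes[idx])
        pos += set_size

    sigma = 0.5
    lam = rng.lognormal(np.log(base_mean) - 0.5 * sigma**2, sigma, n_genes)
    ratio = np.where(affected, effect_ratio, 1.0)
    counts_b = rng.poisson(lam).astype(float)
    counts_a = rng.poisson(lam * ratio).astype(float)

    zero_injected = np.zeros(n_genes, dtype=bool)
    if n_zero_genes:
        # half inside the first affected set, half anywhere else
        aff_idx = np.flatnonzero(affected)
        other_idx = np.flatnonzero(~affected)
        take_aff = min(n_zero_genes // 2, aff_idx.size)
        za = rng.choice(aff_idx, size=take_aff, replace=False)
        zo = rng.choice(other_idx, size=n_zero_genes - take_aff, replace=False)
        zi = np.concatenate([za, zo])
        counts_a[zi[::2]] = 0
        counts_b[zi[1::2]] = 0
        zero_injected[zi] = True

    truth = pd.DataFrame(
        {
            "gene": genes,
            "intensity": lam,
            "true_ratio": ratio,
            "zero_injected": zero_injected,
        }
    )
    fixture = BulkFixture(
        counts_a=pd.Series(counts_a, index=genes, name="count"),
        counts_b=pd.Series(counts_b, index=genes, name="count"),
        gene_sets=gene_sets,
        truth=truth,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts_a": out_dir / "counts_a.tsv",
            "counts_b": out_dir / "counts_b.tsv",
            "gene_sets": out_dir / "gene_sets.gmt",
            "truth": out_dir / "bulk_truth.tsv",
        }
        fixture.counts_a.rename_axis("gene").reset_index().to_csv(
            paths["counts_a"], sep="\t", index=False
        )
        fixture.counts_b.rename_axis("gene").reset_index().to_csv(
            paths["counts_b"], sep="\t", index=False
        )
        sio.write_gmt(gene_sets, paths["gene_sets"])
        truth.to_csv(paths["truth"], sep="\t", index=False)
        fixture.paths = paths
    return fixture


__all__ = [
    "SimConfig",
    "SimResult",
    "BulkFixture",
    "simulate_experiment",
    "simulate_null",
    "simulate_bulk_fixture",
    "CHROM",
]
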