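"""Bulk occupancy / transcriptome integration.

Quantifies transcription-factor occupancy in strand-oriented promoter
windows (1000 bp upstream to 250 bp downstream of the TSS by default),
forms per-gene occupancy ratios between two conditions with zero-count
genes excluded, tests each gene set with a two-sided paired t-test on the
per-gene differences, and provides the pre-ranking score
``log2FC * (-log10 padj)`` used to order genes for enrichment analysis.
Pathway p-values are deliberately not multiplicity-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError


def make_tss_windows(
    genes: pd.DataFrame, upstream: int = 1000, downstream: int = 250
) -> pd.DataFrame:
    """Strand-oriented promoter windows around each gene's TSS.

    ``genes`` needs columns gene, chrom, tss, strand.  A ``+`` gene gets
    ``[tss - upstream, tss + downstream)``; a ``-`` gene the mirror image.
    Negative window starts are clamped to 0 with a warning.
    """
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ConfigurationError(f"gene table missing columns {sorted(missing)}")
    strands = genes["strand"].to_numpy()
    bad = ~np.isin(strands, ["+", "-"])
    if bad.any():
        raise ConfigurationError(
            f"unknown strand symbol(s): {sorted(set(strands[bad]))}"
        )
    tss = genes["tss"].to_numpy()
    plus = strands == "+"
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    if (start < 0).any():
        warnings.warn(
            f"clamped {int((start < 0).sum())} promoter window(s) to base 0"
        )
        start = np.maximum(start, 0)
    return pd.DataFrame(
        {
            "gene": genes["gene"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "tss": tss,
            "strand": strands,
            "start": start,
            "end": end,
        }
    )


def tss_from_bed6(bed: pd.DataFrame) -> pd.DataFrame:
    """Derive gene/TSS records from BED6 gene intervals (TSS at 5' end)."""
    plus = bed["strand"].to_numpy() == "+"
    return pd.DataFrame(
        {
            "gene": bed["name"].to_numpy(),
            "chrom": bed["chrom"].to_numpy(),
            "tss": np.where(plus, bed["start"].to_numpy(), bed["end"].to_numpy() - 1),
            "strand": bed["strand"].to_numpy(),
        }
    )


@dataclass
class PathwayOccupancyResult:
    """Occupancy-ratio summary of one factor over one gene set."""

    pathway: str
    n_genes_used: int
    n_genes_excluded_zero: int
    n_genes_missing: int
    mean_log2_ratio: float
    t_stat: float
    pvalue: float

    @property
    def minus_log10_p(self) -> float:
        return float(-np.log10(self.pvalue)) if np.isfinite(self.pvalue) else np.nan


def occupancy_ratio_test(
    counts_a: pd.Series,
    counts_b: pd.Series,
    gene_set: list[str],
    pathway: str = "",
    log_scale_test: bool = False,
) -> PathwayOccupancyResult:
    """Zero-excluded per-gene occupancy ratios and a paired t-test.

    Genes absent from either count table are dropped (reported); genes with
    a zero count in either condition are excluded to keep the ratio finite.
    ``mean_log2_ratio`` is the mean of per-gene log2(a / b).  The two-sided
    paired t-test runs on the per-gene raw differences ``a - b`` (or on
    log2 values when ``log_scale_test``); fewer than two usable genes, or
    all-zero differences, yield an undefined (NaN) statistic.
    """
    genes = pd.Index(gene_set)
    quantified = genes[genes.isin(counts_a.index) & genes.isin(counts_b.index)]
    n_missing = len(genes) - len(quantified)
    if n_missing:
        warnings.warn(
            f"{pathway or 'gene set'}: dropped {n_missing} gene(s) not quantified"
        )
    a = counts_a.loc[quantified].astype(float)
    b = counts_b.loc[quantified].astype(float)
    nonzero = (a > 0) & (b > 0)
    n_excluded = int((~nonzero).sum())
    a, b = a[nonzero], b[nonzero]

    n_used = len(a)
    if n_used == 0:
        return PathwayOccupancyResult(
            pathway, 0, n_excluded, n_missing, np.nan, np.nan, np.nan
        )
    mean_log2_ratio = float(np.log2(a.to_numpy() / b.to_numpy()).mean())
    if n_used < 2:
        return PathwayOccupancyResult(
            pathway, n_used, n_excluded, n_missing, mean_log2_ratio, np.nan, np.nan
        )
    x, y = (np.log2(a), np.log2(b)) if log_scale_test else (a, b)
    if np.std(x.to_numpy() - y.to_numpy()) == 0:
        t_stat, pvalue = np.nan, np.nan  # degenerate: zero variance of diffs
    else:
        t_stat, pvalue = sps.ttest_rel(x, y)
    return PathwayOccupancyResult(
        pathway, n_used, n_excluded, n_missing,
        mean_log2_ratio, float(t_stat), float(pvalue),
    )


def pathway_occupancy_table(
    counts_a: pd.Series,
    counts_b: pd.Series,
    gene_sets: dict[str, list[str]],
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`occupancy_ratio_test` over a GMT-style gene-set mapping."""
    rows = []
    for name, genes in gene_sets.items():
        res = occupancy_ratio_test(counts_a, counts_b, genes, pathway=name, **kwargs)
        rows.append(
            {
                "pathway": res.pathway,
                "n_genes_used": res.n_genes_used,
                "n_genes_excluded_zero": res.n_genes_excluded_zero,
                "n_genes_missing": res.n_genes_missing,
                "mean_log2_ratio": res.mean_log2_ratio,
                "t_stat": res.t_stat,
                "pvalue": res.pvalue,
                "minus_log10_p": res.minus_log10_p,
            }
        )
    return pd.DataFrame(rows)


def gsea_rank_score(log2fc, padj):
    """Pre-ranking score ``log2fc * (-log10 padj)``; sign follows log2fc."""
    log2fc = np.asarray(log2fc, dtype=float)
    padj = np.asarray(padj, dtype=float)
    if (padj <= 0).any():
        raise ConfigurationError(
            "padj must be > 0 (apply a small floor to zero p-values first)"
        )
    if (padj > 1).any():
        raise ConfigurationError("padj must be <= 1")
    score = log2fc * (-np.log10(padj))
    return float(score) if score.ndim == 0 else score


def de_gene_filter(
    table: pd.DataFrame, min_abs_log2fc: float = 0.5, max_padj: float = 0.1
) -> pd.DataFrame:
    """Significant differential-expression genes: |log2fc| > 0.5 and padj < 0.1.

    Both inequalities are strict.
    """
    missing = {"gene", "log2fc", "padj"} - set(table.columns)
    if missing:
        raise ConfigurationError(f"DE table missing columns {sorted(missing)}")
    keep = (table["log2fc"].abs() > min_abs_log2fc) & (table["padj"] < max_padj)
    return table.loc[keep].reset_index(drop=True)


__all__ = [
    "make_tss_windows",
    "tss_from_bed6",
    "PathwayOccupancyResult",
    "occupancy_ratio_test",
    "pathway_occupancy_table",
    "gsea_rank_score",
    "de_gene_filter",
]
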