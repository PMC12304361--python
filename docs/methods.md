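# Methods

## Model and procedure

`sctagdiff` tests, peak by peak, whether the aggregate targeted-tagmentation
signal of a transcription factor differs between two cell states measured
at single-nucleus resolution.

Each retained peak contributes a window of ±`flank` bp (default 2500)
around the floor of its interval midpoint, divided into `n_b` contiguous
bins of `bin_width` bp (defaults give 100 bins of 50 bp). Fragments are
assigned to (peak, bin) coordinates; the per-condition data structure is a
sparse cells × (peaks · n_b) count matrix.

For one peak with count block `c` (n cells × n_b bins) the statistic uses
the log2 of the bin-averaged, cell-summed signal,
`z̄ = log2(Σ c / n_b)`, with variance

    σ² = 1/(ln2 · n_b) · Σ_{k,l=1..n_b} Σ_{m=1..n} (c_mk − μ̂_k)(c_ml − μ̂_l) / Σ c .

The numerator is the full covariance of the per-cell bin profiles summed
over all bin pairs; cells are treated as independent replicates and bins
within a cell as arbitrarily correlated. Algebraically the double bin sum
equals `Σ_m (r_m − r̄)²` over per-cell row sums `r_m`, which is the
production path (O(n·n_b)); a property test certifies the identity against
the literal quadruple sum at 1e-9 on a thousand random matrices. The
two-condition score is `z = (z̄_A − z̄_B)/√(σ²_A + σ²_B)`, positive when
the first condition is higher. p-values are two-sided standard normal
(the score is a difference of means over a pooled standard error; no other
null family is implied by its construction), adjusted by
Benjamini–Hochberg across all peaks with a computable score; peaks with a
zero total in either condition, or zero pooled variance, carry explicit
status codes and are excluded from the BH family rather than silently
dropped. Selection is `padj < alpha` with `alpha = 0.001`.

### Pipeline order

Testing branch: score filter (≥ 1000) → windows → per-condition matrices →
cell filter (> 250 reads in windows, strict) → per-cell scaling to 10,000
→ z-statistic. QC/embedding branch: additionally the non-zero-peak
quantile filter (drop below the 15% and above the 95% linear-interpolation
quantiles, boundary cells kept) and a natural `log(x+1)` transform, never
applied before testing. The quantile filter's thresholds are recomputed
from the current distribution, so it is intentionally *not* idempotent —
re-application trims further; the read filter and scaling are idempotent.

### Fragment assignment

Default is midpoint assignment: a fragment lands in exactly one bin of
every window containing its midpoint, so window totals conserve fragment
counts and the `Σ c` denominator counts each fragment once. An `overlap`
mode credits every bin the fragment interval intersects (the behaviour of
interval-coverage counting, which multi-counts straddling fragments);
it exists because coverage-based upstream tooling counts this way and the
two modes bracket the plausible conventions. Overlapping peak windows each
receive a fragment independently, consistent with treating peaks as
independent tests.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_score` | 1000 | narrowPeak column-5 threshold (inclusive) |
| `flank`, `bin_width` | 2500 bp, 50 bp | window ±extent and bin size (100 bins) |
| `min_reads` | 250 | strict per-cell in-window read minimum |
| `lower`, `upper` | 0.15, 0.05 | quantile-filter tail fractions on non-zero peaks |
| `target` | 10 000 | per-cell scale total |
| `alpha` | 0.001 | adjusted-p selection threshold |
| `n_components`, `n_neighbors` | 10, 25 | PCA components and kNN size for UMAP |
| TSS window | −1000/+250 bp | strand-oriented promoter quantification extent |
| stability | 20 runs × 80%, threshold 0.75 | subsampling recipe; stable iff median Jaccard strictly above threshold |

Some published analyses trim nuclei at the 2nd coverage percentile instead
of 15%/5%; both are reachable through the `lower`/`upper` parameters.

## Behaviour of the printed variance under scaling

The variance form above is *scale-dependent*: multiplying all counts by a
factor `f` multiplies σ² by `f` (the denominator total is unsquared), so
the score of the same data shrinks by `√f`. Scaling shallow cells (a few
hundred in-window reads) to 10,000 therefore inflates σ² by the scale
factor (~50 at the package's reference depth), and a genuine 4-fold
occupancy change reaches only |z| ≈ 1.5 — correctly *ranked* first
(Spearman agreement with a 999-permutation label-shuffling test is ≈ 0.99)
but not *selected* at padj < 0.001. This is a property of composing the
formula as stated with the prescribed scale-to-10,000 step at that depth;
with deeper cells the scale factor, and hence the variance inflation,
shrinks. A `variance_mode="delta"` alternative implements the standard
first-order delta-method variance of a log-transformed sum,
`n·s_r²/(ln2·Σc)²`, which is scale-invariant and recovers ~80% of planted
4-fold effects at the reference depth with zero empirical false
discoveries. The default remains the form stated above; the alternative is
opt-in and clearly labelled.

## The synthetic-data generator

The simulator emulates exactly the structure the statistic presumes, with
known per-peak truth:

- per peak `p`: baseline intensity `base_p` (lognormal spread around
  `mean_peak_reads`, default 0.4 reads/peak/cell, i.e. ~60 reads per peak
  per condition at 150 cells) and effect `λ_pB = base_p · 2^lfc_p` applied
  to the second condition; a `frac_diff` fraction of peaks (default 10%)
  carries `|lfc| = 2`, signs split evenly;
- per cell: depth factor `d_i ~ LogNormal(−0.125, 0.5)` (unit mean), so
  overdispersion arises from depth mixing; an optional per-bin
  gamma-Poisson (negative binomial) mode adds extra-Poisson noise;
- per bin: weight from a discretised Gaussian centred mid-window
  (`profile_sigma_bins = 3`, i.e. a 150-bp-sd footprint — TF tagmentation
  signal concentrates within ~±200 bp of the summit);
- counts `~ Poisson(d_i · λ_pg · w_j)`, each materialised as a fragment of
  uniform 30–120 bp length whose midpoint stays in its bin (so midpoint and
  overlap counting are both exercised);
- background fragments uniform over the complement of the windows
  (default 50/cell, giving FRiP ≈ 0.76 against the 500-bp peak calls);
- geometry: one synthetic chromosome `chrS`, peak centres spaced
  `2·flank + 1 kb` apart so windows never overlap (an overlapping
  configuration can be built directly from `Peak` records).

Everything is driven by one explicit seed; identical configs give
byte-identical files (gzip members are written with a fixed mtime).

What the simulator does *not* model: chromatin accessibility structure,
fragment-length biology, doublets, batch effects, mappability or blacklist
artefacts, and inter-peak correlation. Passing recovery/null tests
therefore demonstrates correctness of the computation and calibration
under the assumed sampling model, not performance on any real library.

## Bulk integration

Promoter occupancy per gene is quantified in strand-oriented TSS windows
(−1000/+250). Per gene set: genes with a zero count in either condition
are excluded (division by zero), per-gene ratios are summarised as the
mean of log2 ratios (not the log2 of the ratio of means), and significance
comes from a two-sided paired t-test on raw per-gene differences (a
log-scale option exists). Ratio orientation is always explicit — the first
argument is the numerator — because "control/treated" labelling
conventions vary. Pathway p-values are left uncorrected by design: the
intended use is a small, curated set of pathways per factor. The
pre-ranking score for enrichment software is `log2FC · (−log10 padj)`
(sign follows the fold change); a zero adjusted p must be floored by the
caller before scoring.

## Clustering stability and embedding

Cluster stability follows the subsampling recipe: re-cluster 20 random 80%
subsets (clustering is injected as data — this package never chooses the
community-detection algorithm), score each original cluster per run by its
best Jaccard match among the subsample's clusters (0 if no member was
sampled), and call it stable when the median across runs strictly exceeds
0.75. Matching maximises Jaccard per original cluster independently; a
globally-consistent assignment (Hungarian) would also be defensible but
the per-cluster best match is the simpler contract and is invariant to
label renaming. Embedding delegates PCA (10 components), the 25-neighbour
graph and UMAP to scanpy; the package's only numeric promise is
determinism for a fixed seed, and coordinates are for visualisation only.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; even-length intervals take
  the floor of the midpoint.
- Windows that would cross a chromosome boundary are dropped, not clamped,
  so every window keeps exactly `n_b` bins (a single `n_b` is baked into
  the variance formula).
- All-zero blocks return NaN log-signal with `zero_total_*` status; equal
  means with zero pooled variance give `z = 0` (`zero_variance` status);
  unequal means with zero variance give NaN.
- BH is computed with statsmodels; quantiles with numpy linear
  interpolation; paired t with scipy. The sparse matrix round-trips through
  a plain-text triplet + companion-table layout with full float precision.
- Threshold comparisons follow their sources exactly: score ≥ 1000
  inclusive, reads > 250 strict, |log2FC| > 0.5 and padj < 0.1 strict,
  median Jaccard > 0.75 strict.

## Known limitations

- Two conditions only; no covariates, no shrinkage or empirical-Bayes
  moderation of the per-peak variance.
- The normal null for `z` is asserted, not derived; empirically the null
  z-distribution on simulated exchangeable data is symmetric around zero
  and label-permutation invariant (KS), but tail calibration inherits the
  scale-dependence discussed above.
- Windows are centred on interval midpoints; summit-based centring
  (narrowPeak column 10) is deliberately not implemented.
- BAM/SAM input is out of scope: fragments enter as (chrom, start, end,
  barcode[, count]) text, the exchange format upstream aligners can emit.
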