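# sctagdiff

Differential transcription-factor (TF) occupancy analysis for single-cell
targeted-tagmentation data (CUT&Tag-style assays), plus the bulk
promoter-occupancy / transcriptome integration that typically accompanies
such experiments.

Antibody-directed tagmentation assays read out TF–DNA binding as sequenced
fragments concentrated at peaks. At single-nucleus resolution the counts
per cell are extremely sparse, so `sctagdiff` tests each peak *in
aggregate* across cells while propagating the cell-to-cell variability of
the signal into the test statistic.

## The statistic

For one peak, let `c` be the `n × n_b` matrix of fragment counts (cells ×
fixed-width bins across the ±2.5 kb window around the peak centre,
`n_b = 100` bins of 50 bp by default). The log signal and its variance are

    z̄  = log2( (1/n_b) · Σ_i Σ_j c_ij )

    σ² = 1/(ln2 · n_b) · [ Σ_{k,l} Σ_m (c_mk − μ̂_k)(c_ml − μ̂_l) ] / Σ_ij c_ij

with `μ̂_j` the per-bin cell average. The double bin sum keeps the full
bin–bin covariance of the per-cell profiles; internally it is computed via
the algebraic identity with the per-cell row-sum deviations,
`Σ_m (r_m − r̄)²`, in O(n·n_b). Two conditions A and B are compared per
peak by

    z = (z̄_A − z̄_B) / sqrt(σ²_A + σ²_B),

two-sided normal p-values are adjusted across peaks by Benjamini–Hochberg,
and peaks with adjusted p < 0.001 are selected. Positive `z` means higher
occupancy in condition A.

Around the statistic the package provides the full pipeline: narrowPeak /
fragment / design-table IO, peak-score filtering (≥ 1000), window binning,
per-condition cell × (peak, bin) sparse matrices, cell QC (> 250 reads in
windows; 15%/5% non-zero-peak quantile filter for the embedding branch),
per-cell scaling to 10,000, FRiP, PCA/UMAP embedding, Jaccard
cluster-stability scoring, strand-oriented TSS windows (−1000/+250 bp),
zero-excluded occupancy ratios with paired t-tests per gene set, the
`log2FC × (−log10 padj)` pre-ranking score, and a fully seeded simulator
with per-peak ground truth.

## Worked example

Simulate a two-state experiment (500 peaks, 10% differentially occupied at
|log2FC| = 2, 150 cells per state), count, QC and test — all from the
shell:

```bash
sctagdiff simulate --seed 5 --out-dir sim
zcat sim/fragments_A.tsv.gz sim/fragments_B.tsv.gz > fragments.tsv
sctagdiff windows --peaks sim/peaks.narrowPeak --out windows.bed
sctagdiff count --fragments fragments.tsv --peaks sim/peaks.narrowPeak \
                --design sim/design.tsv --out-dir mats
sctagdiff frip --fragments fragments.tsv --peaks sim/peaks.narrowPeak
sctagdiff test --matrix-a mats/A --matrix-b mats/B --min-reads 100 \
               --out results.tsv
```

which prints

```
wrote 77799 fragments over 500 peaks to sim
500 windows (100 bins x 50 bp); dropped 0
A: 150 cells x 500 peaks
B: 150 cells x 500 peaks
pooled FRiP: 0.7600
0/500 peaks selected at padj < 0.001
```

`results.tsv` holds one row per peak (`peak, zbar_a, zbar_b, var_a, var_b,
z, pvalue, padj, selected, status`). A FRiP of 0.76 says three quarters of
all fragments fall inside called peaks — a clean library. At this
simulated sequencing depth (~60 reads per peak per condition) the default
statistic ranks the truly differential peaks first (they carry the largest
|z|) but no peak clears the stringent padj < 0.001 cut after per-cell
scaling; see `docs/methods.md` for the depth/scaling analysis and the
scale-invariant `--variance-mode delta` alternative, which recovers most
of the planted effects on the same data.

The same steps are available as library calls (`sctagdiff.simulate_experiment`,
`build_matrix`, `normalize_total`, `run_differential`, ...).

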