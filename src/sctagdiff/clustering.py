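"""Embedding of cells and resampling-based cluster-stability assessment.

The embedding contract is deliberately thin: scaled, log-transformed counts
restricted to the differential peaks are reduced to a few principal
components, a k-nearest-neighbour graph is built, and a 2-D UMAP layout is
produced — all delegated to scanpy, with determinism for a fixed seed as the
only numeric guarantee.  Cluster stability follows the subsampling recipe:
recluster repeated 80% subsamples, score each original cluster by its
best-match Jaccard index per run, and call it stable when the median across
runs exceeds 0.75 (strictly).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PipelineError
from .matrix import BinnedCountMatrix


def embed_cells(
    matrix: BinnedCountMatrix,
    n_components: int = 10,
    n_neighbors: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP coordinates per cell (PCA -> kNN graph -> UMAP).

    Requires a scaled, log(x + 1)-transformed matrix (typically restricted
    beforehand to the selected differential peaks) and strictly more cells
    than ``n_neighbors``.  Coordinates are for visualisation only; the same
    input and seed always give identical output.
    """
    import anndata as ad
    import scanpy as sc

    if not (matrix.scaled and matrix.log_transformed):
        raise PipelineError("embedding expects scaled, log1p-transformed counts")
    if matrix.n_cells <= n_neighbors:
        raise ConfigurationError(
            f"need more than n_neighbors={n_neighbors} cells, "
            f"got {matrix.n_cells}"
        )
    adata = ad.AnnData(
        X=matrix.counts.astype(np.float32).copy(),
        obs=pd.DataFrame(index=matrix.cell_ids.astype(str)),
    )
    n_comps = min(n_components, matrix.n_cells - 1, adata.n_vars - 1)
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.umap(adata, random_state=seed)
    return np.asarray(adata.obsm["X_umap"], dtype=float)


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; 0 by convention (with a warning) when both empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard index of two empty sets taken as 0 by convention")
        return 0.0
    return len(a & b) / len(union)


def cluster_stability(
    full_labels: Mapping | pd.Series,
    subsample_runs: Sequence[tuple[Iterable, Mapping | pd.Series]],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Best-match Jaccard stability of each original cluster across subsamples.

    ``full_labels`` maps every cell to its cluster in the full-data
    clustering; each run is ``(subsampled cell ids, cell -> cluster map)``
    from re-clustering that subsample.  For each original cluster and run,
    the cluster is restricted to the run's cells and compared against every
    subsample cluster, keeping the best Jaccard (0 if no member was
    sampled).  A cluster is stable when its median across runs is strictly
    above ``threshold``.  Matching is by best overlap, so the report is
    invariant to cluster-label renaming.
    """
    full = pd.Series(full_labels)
    full_cells = set(full.index)
    if not subsample_runs:
        raise ConfigurationError("at least one subsample run is required")
    members = {lab: set(idx) for lab, idx in full.groupby(full).groups.items()}

    per_cluster: dict = {lab: [] for lab in members}
    for run_i, (cells, labels) in enumerate(subsample_runs):
        cells = set(cells)
        if not cells:
            raise ConfigurationError(f"subsample run {run_i} is empty")
        if not cells <= full_cells:
            raise ConfigurationError(
                f"subsample run {run_i} contains cells outside the full set"
            )
        sub = pd.Series(labels)
        sub_members = [set(idx) for _, idx in sub.groupby(sub).groups.items()]
        for lab, cell_set in members.items():
            restricted = cell_set & cells
            if not restricted:
                per_cluster[lab].append(0.0)
                continue
            best = max(
                (jaccard_index(restricted, s) for s in sub_members), default=0.0
            )
            per_cluster[lab].append(best)

    rows = []
    for lab, values in per_cluster.items():
        med = float(np.median(values))
        rows.append(
            {
                "cluster": lab,
                "jaccard_values": values,
                "median_jaccard": med,
                "stable": med > threshold,
            }
        )
    return pd.DataFrame(rows)


__all__ = ["embed_cells", "jaccard_index", "cluster_stability"]
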