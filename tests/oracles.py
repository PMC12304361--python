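"""Independent naive reference implementations used only to check the package.

These deliberately avoid the production code paths: the variance is the
literal double bin sum over all (k, l) bin pairs (and, for tiny inputs, a
pure-Python quadruple loop), the differential table is computed peak by
peak, and permutation p-values come from explicit label reshuffling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)


def naive_mean_log_signal(c: np.ndarray) -> float:
    c = np.asarray(c, dtype=float)
    return float(np.log2(c.sum() / c.shape[1]))


def naive_log_variance(c: np.ndarray) -> float:
    """Literal formula: all n_b^2 bin-pair covariance terms via einsum."""
    c = np.asarray(c, dtype=float)
    n, nb = c.shape
    dev = c - c.mean(axis=0)
    quad = float(np.einsum("mk,ml->", dev, dev))
    return quad / (LN2 * nb * c.sum())


def quadruple_loop_variance(c: np.ndarray) -> float:
    """Pure-Python quadruple loop; only for very small blocks."""
    c = np.asarray(c, dtype=float)
    n, nb = c.shape
    mu = [sum(c[m][j] for m in range(n)) / n for j in range(nb)]
    quad = 0.0
    for k in range(nb):
        for l in range(nb):
            for m in range(n):
                quad += (c[m][k] - mu[k]) * (c[m][l] - mu[l])
    return quad / (LN2 * nb * c.sum())


def naive_zscore(c_a: np.ndarray, c_b: np.ndarray) -> float:
    za, va = naive_mean_log_signal(c_a), naive_log_variance(c_a)
    zb, vb = naive_mean_log_signal(c_b), naive_log_variance(c_b)
    return (za - zb) / np.sqrt(va + vb)


def naive_differential(matrix_a, matrix_b, alpha: float = 0.001) -> pd.DataFrame:
    """Peak-by-peak differential table on dense blocks, BH via statsmodels."""
    rows = []
    for pid in matrix_a.peak_ids:
        ca = matrix_a.peak_block(pid)
        cb = matrix_b.peak_block(pid)
        rows.append((pid, naive_zscore(ca, cb)))
    df = pd.DataFrame(rows, columns=["peak", "z"])
    df["pvalue"] = 2 * sps.norm.sf(df["z"].abs())
    df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    df["selected"] = df["padj"] < alpha
    return df


def permutation_pvalues(
    matrix_a, matrix_b, n_perm: int = 999, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Label-shuffling permutation p-values for every peak.

    Returns ``(z_observed, p_perm)`` where ``p_perm`` uses the add-one
    estimator ``(1 + #{|z_perm| >= |z_obs|}) / (n_perm + 1)``.
    """
    r_a = matrix_a.peak_cell_sums()
    r_b = matrix_b.peak_cell_sums()
    pooled = np.vstack([r_a, r_b])
    n_a, n_cells, nb = r_a.shape[0], pooled.shape[0], matrix_a.n_bins

    def zvec(idx_a, idx_b):
        ta, tb = pooled[idx_a].sum(0), pooled[idx_b].sum(0)
        ssa = ((pooled[idx_a] - pooled[idx_a].mean(0)) ** 2).sum(0)
        ssb = ((pooled[idx_b] - pooled[idx_b].mean(0)) ** 2).sum(0)
        va, vb = ssa / (LN2 * nb * ta), ssb / (LN2 * nb * tb)
        return (np.log2(ta / nb) - np.log2(tb / nb)) / np.sqrt(va + vb)

    z_obs = zvec(np.arange(n_a), np.arange(n_a, n_cells))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(pooled.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n_cells)
        exceed += np.abs(zvec(perm[:n_a], perm[n_a:])) >= np.abs(z_obs)
    return z_obs, (1.0 + exceed) / (n_perm + 1.0)
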