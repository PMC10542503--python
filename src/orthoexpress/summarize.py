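"""Global expression summaries: sample correlation matrix and PCA.

Both operate on log2(CPM + pseudocount) matrices, the conventional view
for between-sample expression comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

__all__ = ["sample_correlation_matrix", "pca"]


def sample_correlation_matrix(
    log_cpm: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between samples over loci, plus a
    dendrogram leaf ordering (average linkage on 1 - r).

    Zero-variance samples get NaN correlations (flagged undefined) and
    are placed at the end of the ordering.
    """
    if log_cpm.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = log_cpm.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = pd.DataFrame(corr, index=log_cpm.columns, columns=log_cpm.columns)
    ok = sd > 0
    np.fill_diagonal(corr.values, np.where(ok, 1.0, np.nan))
    good = [s for s, flag in zip(log_cpm.columns, ok) if flag]
    if len(good) >= 3:
        sub = corr.loc[good, good].to_numpy()
        d = np.clip(1.0 - sub, 0.0, None)
        np.fill_diagonal(d, 0.0)
        order_idx = leaves_list(average(squareform(d, checks=False)))
        ordering = [good[i] for i in order_idx]
    else:
        ordering = good
    ordering += [s for s, flag in zip(log_cpm.columns, ok) if not flag]
    return corr, ordering


def pca(
    log_cpm: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples with loci as features.

    The matrix is centered per locus (no scaling) and decomposed by
    SVD.  Returns sample scores and the variance fractions of the
    reported axes (non-increasing; summing to <= 1).  Sign convention:
    the largest-magnitude locus loading on each axis is positive.
    """
    n_samples = log_cpm.shape[1]
    if n_samples < 3:
        raise ValueError("need at least three samples")
    if n_components > n_samples:
        raise ValueError("more components requested than samples")
    x = log_cpm.to_numpy(dtype=float)
    centered = (x - x.mean(axis=1, keepdims=True)).T  # samples x loci
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float((s**2).sum())
    k = n_components
    scores = u[:, :k] * s[:k]
    for axis in range(k):
        lead = np.argmax(np.abs(vt[axis]))
        if vt[axis, lead] < 0:
            vt[axis] *= -1
            scores[:, axis] *= -1
    var_frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    score_df = pd.DataFrame(
        scores, index=log_cpm.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return score_df, var_frac
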