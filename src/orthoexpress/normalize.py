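"""TMM normalization and CPM transforms.

The trimmed mean of M-values (TMM) scaling factor for a sample compares
it with a reference sample via locus-wise log-ratios of relative
abundance (M-values).  Loci with extreme M (default top/bottom 30%) or
extreme average abundance A (default top/bottom 5%) are discarded and
the remaining M-values averaged with inverse asymptotic-binomial-variance
weights.  The factor is ``2**weighted_mean_M``; factors are rescaled so
their geometric mean is exactly 1.  Counts per million divide each count
by the sample's effective library size (raw library size x TMM factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import CountMatrix

__all__ = [
    "NormalizationFactors",
    "compute_tmm_factors",
    "cpm_matrix",
    "filter_low_expression",
]


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors (geometric mean 1) plus provenance."""

    factors: pd.Series
    reference: str
    trim_m: float = 0.30
    trim_a: float = 0.05

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")

    def effective_lib_sizes(self, cm: CountMatrix) -> pd.Series:
        return cm.lib_sizes() * self.factors


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference sample."""
    ok = (obs > 0) & (ref > 0)
    y, r = obs[ok].astype(float), ref[ok].astype(float)
    if y.size == 0:
        return 1.0
    m = np.log2((y / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((y / n_obs) * (r / n_ref))
    # asymptotic variance of M under binomial sampling; weight = 1/v
    v = (n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def compute_tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors for every sample.

    The reference sample is the one whose 75th percentile of relative
    abundance is closest to the across-sample mean, unless ``ref_sample``
    is given explicitly.
    """
    if not (0 <= trim_m < 0.5) or not (0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"sample {cm.sample_ids[zero[0]]!r} has all-zero counts")
    if ref_sample is None:
        f75 = np.quantile(counts / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(cm.sample_ids).index(ref_sample)
    ref = counts[:, ref_idx]
    fac = np.array(
        [
            _tmm_pair_factor(counts[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    fac /= np.exp(np.mean(np.log(fac)))
    return NormalizationFactors(
        factors=pd.Series(fac, index=cm.sample_ids, name="tmm_factor"),
        reference=str(cm.sample_ids[ref_idx]),
        trim_m=trim_m,
        trim_a=trim_a,
    )


def cpm_matrix(
    cm: CountMatrix,
    factors: NormalizationFactors | None = None,
    log2_transform: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Counts per million on effective library sizes.

    ``CPM = count / (lib_size * factor) * 1e6``; with ``log2_transform``
    the result is ``log2(CPM + pseudocount)``.
    """
    if factors is not None and list(factors.factors.index) != list(cm.sample_ids):
        raise ValueError("normalization factors computed on different samples")
    lib = cm.lib_sizes().to_numpy(dtype=float)
    if factors is not None:
        lib = lib * factors.factors.to_numpy()
    cpm = cm.counts.to_numpy(dtype=float) / lib * 1e6
    if log2_transform:
        cpm = np.log2(cpm + pseudocount)
    return pd.DataFrame(cpm, index=cm.locus_ids, columns=cm.sample_ids)


def filter_low_expression(
    cm: CountMatrix,
    factors: NormalizationFactors | None = None,
    min_cpm: float = 1.0,
) -> CountMatrix:
    """Optional low-expression filter: keep loci reaching ``min_cpm`` in
    at least one sample.  Off by default in the pipeline; the main
    analysis keeps all loci."""
    cpm = cpm_matrix(cm, factors)
    keep = (cpm >= min_cpm).any(axis=1)
    return cm.subset_loci(cm.locus_ids[keep.to_numpy()])
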