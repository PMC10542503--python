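"""Negative-binomial differential expression between taxa.

The model is the classic count-based one: the count for locus *g* in a
replicate of taxon *t* is NB with mean ``mu_gt`` and common dispersion
``phi`` (variance ``mu + phi * mu**2``; ``phi = 0`` degenerates to
Poisson).  Dispersion is estimated by maximizing the conditional
log-likelihood (conditioning on per-group totals) on library-size
equalized counts, and each ordered pair of taxa is compared with an
exact conditional test of the group-A total given the overall total.
P-values are Benjamini-Hochberg adjusted; a locus is differentially
expressed (DE) when q < alpha (strictly), with no fold-change cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix
from .normalize import NormalizationFactors

__all__ = [
    "DispersionEstimate",
    "equalize_libraries",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_de",
    "de_pair",
    "de_all_pairs",
    "DIRECTION_UP_FIRST",
    "DIRECTION_UP_SECOND",
    "DIRECTION_NONE",
]

DIRECTION_UP_FIRST = "up_in_first"
DIRECTION_UP_SECOND = "up_in_second"
DIRECTION_NONE = "none"


@dataclass
class DispersionEstimate:
    """Common NB dispersion (phi >= 0) and how it was obtained."""

    phi: float
    method: str = "conditional_ml"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be non-negative")


def equalize_libraries(
    cm: CountMatrix, factors: NormalizationFactors | None = None
) -> pd.DataFrame:
    """Scale counts to a common (geometric-mean) effective library size.

    Returns integer pseudo-counts; the conditional likelihood and the
    exact test are only well defined when all libraries are equal.
    """
    lib = cm.lib_sizes().to_numpy(dtype=float)
    if factors is not None:
        lib = lib * factors.factors.to_numpy()
    if (lib <= 0).any():
        bad = cm.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has non-positive library size")
    target = np.exp(np.mean(np.log(lib)))
    scaled = np.rint(cm.counts.to_numpy(dtype=float) * (target / lib)).astype(np.int64)
    return pd.DataFrame(scaled, index=cm.locus_ids, columns=cm.sample_ids)


def _group_cond_loglik(y: np.ndarray, phi: float) -> float:
    """Conditional (on the row total) log-likelihood of one group.

    ``y`` is an n_reps x n_loci integer array.  For NB(mu, phi) counts
    with equal means within the group, the totals-conditional pmf is a
    Dirichlet-multinomial that depends only on r = 1/phi.
    """
    n, _ = y.shape
    z = y.sum(axis=0)
    const = gammaln(z + 1.0) - gammaln(y + 1.0).sum(axis=0)
    if phi < 1e-12:
        # Poisson limit: symmetric multinomial
        return float(np.sum(const - z * np.log(n)))
    r = 1.0 / phi
    ll = (
        gammaln(y + r).sum(axis=0)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
        + const
    )
    return float(ll.sum())


def estimate_common_dispersion(
    cm: CountMatrix,
    factors: NormalizationFactors | None = None,
    grid: tuple[float, float, int] = (1e-6, 5.0, 41),
) -> DispersionEstimate:
    """Single common dispersion by conditional maximum likelihood.

    A log-spaced grid search is refined with bounded scalar
    minimization; the Poisson limit (phi = 0) is considered explicitly.
    Requires at least one taxon with >= 2 replicates.
    """
    eq = equalize_libraries(cm, factors)
    if not eq.to_numpy().any():
        raise ValueError("all-zero count matrix")
    groups = [
        eq[cm.samples_of(t)].to_numpy().T
        for t in cm.taxa
        if len(cm.samples_of(t)) >= 2
    ]
    if not groups:
        raise ValueError("no taxon has >= 2 replicates")

    def nll(log_phi: float) -> float:
        return -sum(_group_cond_loglik(y, float(np.exp(log_phi))) for y in groups)

    lo, hi, n_grid = grid
    log_grid = np.log(np.geomspace(lo, hi, n_grid))
    vals = np.array([nll(lp) for lp in log_grid])
    best = int(np.argmin(vals))
    ll_zero = sum(_group_cond_loglik(y, 0.0) for y in groups)
    if -vals[best] <= ll_zero + 1e-9 or best == 0:
        return DispersionEstimate(phi=0.0)
    bracket = (log_grid[max(best - 1, 0)], log_grid[min(best + 1, n_grid - 1)])
    res = minimize_scalar(nll, bounds=bracket, method="bounded")
    phi = float(np.exp(res.x)) if res.fun <= vals[best] else float(np.exp(log_grid[best]))
    return DispersionEstimate(phi=max(phi, 0.0))


def _cond_exact_pvalue(za: int, zb: int, n_a: int, n_b: int, phi: float) -> float:
    """Doubled smaller-tail conditional p-value, capped at 1.

    With equal per-sample libraries the group totals are NB with sizes
    ``n_a/phi`` and ``n_b/phi``; conditional on the grand total ``z``
    the group-A total follows a beta-binomial-type pmf over 0..z.  For
    phi = 0 the conditional law is Binomial(z, n_a/(n_a+n_b)).
    """
    z = za + zb
    if z == 0:
        return 1.0
    if phi < 1e-12:
        p0 = n_a / (n_a + n_b)
        lower = binom.cdf(za, z, p0)
        upper = binom.sf(za - 1, z, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    ra, rb = n_a / phi, n_b / phi
    k = np.arange(z + 1)
    logw = (
        gammaln(k + ra)
        - gammaln(k + 1.0)
        + gammaln(z - k + rb)
        - gammaln(z - k + 1.0)
    )
    logw -= logsumexp(logw)
    w = np.exp(logw)
    lower = float(w[: za + 1].sum())
    upper = float(w[za:].sum())
    return float(min(1.0, 2.0 * min(lower, upper)))


def nb_exact_test(
    cm: CountMatrix,
    taxon_a: str,
    taxon_b: str,
    dispersion: float | DispersionEstimate,
    factors: NormalizationFactors | None = None,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Per-locus exact test of ``taxon_b`` vs ``taxon_a``.

    Returns a DataFrame indexed by locus with columns ``log2fc`` (second
    vs first taxon, with ``prior_count`` added to each normalized group
    mean) and ``pvalue``.
    """
    phi = dispersion.phi if isinstance(dispersion, DispersionEstimate) else float(dispersion)
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    cols_a, cols_b = cm.samples_of(taxon_a), cm.samples_of(taxon_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both taxa need >= 2 replicates for the exact test")
    eq = equalize_libraries(cm, factors)
    ya = eq[cols_a].to_numpy()
    yb = eq[cols_b].to_numpy()
    za, zb = ya.sum(axis=1), yb.sum(axis=1)
    n_a, n_b = len(cols_a), len(cols_b)
    pvals = np.array(
        [_cond_exact_pvalue(int(a), int(b), n_a, n_b, phi) for a, b in zip(za, zb)]
    )
    mean_a = za / n_a
    mean_b = zb / n_b
    log2fc = np.log2((mean_b + prior_count) / (mean_a + prior_count))
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals}, index=cm.locus_ids
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag DE loci at FDR < alpha (strict); no fold-change cutoff.

    Adds ``qvalue``, ``de_flag`` and ``direction`` columns.  Direction
    follows the sign of ``log2fc`` for flagged loci and is ``"none"``
    otherwise.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    out = results.copy()
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["de_flag"] = out["qvalue"] < alpha
    direction = np.where(
        ~out["de_flag"],
        DIRECTION_NONE,
        np.where(out["log2fc"] > 0, DIRECTION_UP_SECOND, DIRECTION_UP_FIRST),
    )
    direction[(out["de_flag"]) & (out["log2fc"] == 0)] = DIRECTION_NONE
    out["direction"] = direction
    return out


def de_pair(
    cm: CountMatrix,
    taxon_a: str,
    taxon_b: str,
    dispersion: float | DispersionEstimate,
    factors: NormalizationFactors | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact test + BH + DE call for one ordered taxon pair."""
    return call_de(
        nb_exact_test(cm, taxon_a, taxon_b, dispersion, factors), alpha=alpha
    )


def de_all_pairs(
    cm: CountMatrix,
    pairs: list[tuple[str, str]] | None = None,
    factors: NormalizationFactors | None = None,
    dispersion: float | DispersionEstimate | None = None,
    alpha: float = 0.05,
) -> dict[tuple[str, str], pd.DataFrame]:
    """DE tables for every ordered taxon pair (all six by default)."""
    if pairs is None:
        taxa = cm.taxa
        pairs = [(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1 :]]
    if dispersion is None:
        dispersion = estimate_common_dispersion(cm, factors)
    return {
        (a, b): de_pair(cm, a, b, dispersion, factors, alpha) for a, b in pairs
    }
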