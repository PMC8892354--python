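"""Two-group negative-binomial differential expression.

A self-contained stand-in for the edgeR classic pipeline: TMM library
normalization, a method-of-moments common dispersion, the conditional NB
exact test on group-summed counts, and Benjamini-Hochberg FDR. It is not a
clone of edgeR — dispersion is a moment estimate rather than conditional
maximum likelihood, and library sizes are equalized by scaling + rounding
before the exact test — but the downstream screens depend only on the FDR
gate, not on edgeR internals.

The NB parameterization throughout is variance = mu + phi * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, rankdata

from .quantify import CountMatrix

__all__ = [
    "tmm_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "run_de",
    "DispersionEstimate",
]

# Relative tie tolerance when summing partitions at least as extreme as the
# observed one (same convention as scipy.stats.binomtest two-sided).
_TIE_RTOL = 1e-7


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """TMM factor of one sample against the reference (edgeR-style)."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("sample shares no expressed features with reference")
    o, r = obs[keep], ref[keep]
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M as inverse weight
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not trimmed.any() or w[trimmed].sum() == 0:
        return 1.0
    f = np.sum(w[trimmed] * m[trimmed]) / np.sum(w[trimmed])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    cm: CountMatrix,
    reference: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    M-values are trimmed 30% in each tail and A-values 5% in each tail
    (defaults); the weighted mean of the surviving M-values gives the
    per-sample factor, renormalized to geometric mean 1. ``reference=None``
    picks the sample whose upper-quartile (depth-scaled) is closest to the
    mean upper-quartile.
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample column")
    if reference is None:
        f75 = np.percentile(mat / lib, 75, axis=0)
        reference = counts.columns[int(np.argmin(np.abs(f75 - f75.mean())))]
    ref_idx = counts.columns.get_loc(reference)
    factors = np.ones(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref_idx:
            continue
        factors[k] = _tmm_pair(
            mat[:, k], mat[:, ref_idx], lib[k], lib[ref_idx], logratio_trim, sum_trim
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


@dataclass
class DispersionEstimate:
    """Common NB dispersion plus the per-gene moment estimates behind it."""

    common: float
    per_gene: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.common) or self.common < 0:
            raise ValueError("common dispersion must be finite and >= 0")


def _normalized_counts(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts rescaled to a common effective library size (geometric mean)."""
    if factors is None:
        factors = tmm_factors(cm)
    lib = cm.counts.sum(axis=0)
    eff = lib * factors
    target = np.exp(np.mean(np.log(eff)))
    return cm.counts * (target / eff)


def estimate_dispersion(
    cm: CountMatrix,
    groups: dict[str, list[str]],
    factors: pd.Series | None = None,
) -> DispersionEstimate:
    """Method-of-moments common dispersion on normalized counts.

    Per gene, phi_g = max(0, (s2_g - mean_g) / mean_g^2) where s2_g pools the
    within-group sample variances; the common value is the median over genes
    with mean > 1. Because a median across genes is taken, the pooled
    variance is first rescaled by the median of chi^2_d/d at its pooled
    degrees of freedom d (median-unbiasedness correction; the raw median
    underestimates the dispersion by ~16% at d = 4 and makes the exact test
    anti-conservative). Requires replication in at least one group.
    """
    replicated = {g: s for g, s in groups.items() if len(s) >= 2}
    if not replicated:
        raise ValueError("no group with >= 2 replicates")
    norm = _normalized_counts(cm, factors)
    used = [s for samples in replicated.values() for s in samples]
    mean_g = norm[used].mean(axis=1)
    ss = pd.Series(0.0, index=norm.index)
    dof = 0
    for samples in replicated.values():
        sub = norm[samples]
        ss += sub.sub(sub.mean(axis=1), axis=0).pow(2).sum(axis=1)
        dof += len(samples) - 1
    s2 = ss / dof
    s2 = s2 / (chi2.median(dof) / dof)  # median-unbiased pooled variance
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_g = ((s2 - mean_g) / mean_g**2).clip(lower=0.0).fillna(0.0)
    informative = phi_g[mean_g > 1]
    common = float(informative.median()) if len(informative) else 0.0
    return DispersionEstimate(common=max(common, 0.0), per_gene=phi_g)


def _conditional_logpmf(total: int, n_a: float, n_b: float, phi: float) -> np.ndarray:
    """log P(A = a | A + B = total) for a = 0..total.

    A is the sum of n_a i.i.d. NB(mu, phi) counts, B of n_b; with equalized
    per-sample means the NB success probability cancels and the conditional
    law depends only on the shape totals r_a = n_a/phi, r_b = n_b/phi. At
    phi = 0 the Poisson limit gives Binomial(total, n_a/(n_a+n_b)).
    """
    a = np.arange(total + 1, dtype=float)
    if phi == 0.0:
        logp = np.log(n_a / (n_a + n_b))
        logq = np.log(n_b / (n_a + n_b))
        logw = (
            gammaln(total + 1)
            - gammaln(a + 1)
            - gammaln(total - a + 1)
            + a * logp
            + (total - a) * logq
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logw = (
            gammaln(r_a + a)
            - gammaln(a + 1)
            + gammaln(r_b + total - a)
            - gammaln(total - a + 1)
        )
        logw -= logsumexp(logw)
    return logw


def nb_exact_test(y_a: float, y_b: float, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional NB exact test on group-summed counts.

    Counts are assumed pre-equalized to a common effective library size.
    The p-value sums, over all partitions a + b of the observed total, the
    conditional probabilities no larger than that of the observed partition
    (minimum-likelihood two-sided rule, ties included).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if y_a < 0 or y_b < 0:
        raise ValueError("negative counts")
    y_a, y_b = int(round(y_a)), int(round(y_b))
    total = y_a + y_b
    if total == 0:
        return 1.0
    logw = _conditional_logpmf(total, n_a, n_b, phi)
    cutoff = logw[y_a] + np.log1p(_TIE_RTOL)
    mask = logw <= cutoff
    return float(min(1.0, np.exp(logsumexp(logw[mask]) - logsumexp(logw))))


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(arr)
    if m == 0:
        return p if isinstance(p, pd.Series) else arr
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="fdr")
    return out


def run_de(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    phi: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """TMM -> dispersion -> per-gene NB exact test -> BH.

    Returns a DataFrame (feature index) with ``logFC`` (A over B, from
    normalized means with a pseudocount), ``pvalue`` and ``fdr``. Genes with
    zero counts in every sample get p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both contrast groups must be non-empty")
    sub = cm.subset_samples(group_a + group_b)
    factors = tmm_factors(sub) if sub.counts.shape[1] >= 2 else None
    if phi is None:
        phi = estimate_dispersion(sub, {"A": group_a, "B": group_b}, factors).common
    norm = _normalized_counts(sub, factors)
    equalized = norm.round().astype(np.int64)
    ya = equalized[group_a].sum(axis=1).to_numpy()
    yb = equalized[group_b].sum(axis=1).to_numpy()
    n_a, n_b = len(group_a), len(group_b)
    pvals = np.ones(len(ya))
    for i in range(len(ya)):
        if ya[i] + yb[i] > 0:
            pvals[i] = nb_exact_test(ya[i], yb[i], n_a, n_b, phi)
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    logfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    result = pd.DataFrame(
        {"logFC": logfc, "pvalue": pvals, "fdr": bh_adjust(pvals)},
        index=sub.counts.index,
    )
    result.index.name = "feature_id"
    return result
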