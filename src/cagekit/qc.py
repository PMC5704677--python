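"""Replicate QC and between-sample normalization.

TMM (trimmed mean of M-values) scaling factors and classical MDS on
leading log-fold-change distances are implemented here directly; Spearman
correlation is delegated to scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05


@dataclass
class NormalizedMatrix:
    counts: pd.DataFrame        # peaks x samples, raw integer counts
    library_sizes: pd.Series
    factors: pd.Series          # geometric mean 1
    normalized: pd.DataFrame    # count / (libsize * factor) * 1e6

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, **tmm_kwargs) -> "NormalizedMatrix":
        lib = counts.sum(axis=0).astype(float)
        factors = tmm_factors(counts, **tmm_kwargs)
        norm = counts / (lib * factors) * 1e6
        return cls(counts=counts, library_sizes=lib, factors=factors, normalized=norm)


def _rank(values: np.ndarray) -> np.ndarray:
    """1-based average ranks (matches R's rank())."""
    return stats.rankdata(values, method="average")


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
    reference: str | int = "auto",
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Per sample vs the reference: gene-wise M (log2 ratio of library-scaled
    proportions) and A (average log2 abundance) are computed over genes
    nonzero in both; the top/bottom ``trim_m`` of M-ranks and ``trim_a``
    of A-ranks are discarded; the factor is 2 to the precision-weighted
    mean of the remaining M values. The reference column is the sample
    whose upper-quartile proportion is closest to the mean upper quartile
    when ``reference='auto'``.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts")
    lib = mat.sum(axis=0)
    for j, tot in enumerate(lib):
        if tot == 0:
            raise ValueError(f"sample {counts.columns[j]!r} has all-zero counts")
    if reference == "auto":
        f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref = counts.columns.get_loc(reference) if isinstance(reference, str) else int(reference)
    r = mat[:, ref]
    nr = lib[ref]
    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        x = mat[:, j]
        n = lib[j]
        keep = (x > 0) & (r > 0)
        if not keep.any():
            logger.warning("no co-expressed genes between %s and reference; factor 1",
                           counts.columns[j])
            continue
        xk, rk = x[keep], r[keep]
        m = np.log2((xk / n) / (rk / nr))
        a = 0.5 * np.log2((xk / n) * (rk / nr))
        # asymptotic variance of M; precision weights are its inverse
        v = (n - xk) / (n * xk) + (nr - rk) / (nr * rk)
        w = 1.0 / v
        if np.max(np.abs(m)) < 1e-6:
            continue
        ng = len(m)
        lo_m = np.floor(ng * trim_m) + 1
        hi_m = ng + 1 - lo_m
        lo_a = np.floor(ng * trim_a) + 1
        hi_a = ng + 1 - lo_a
        rank_m = _rank(m)
        rank_a = _rank(a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any() or w[sel].sum() == 0:
            continue
        log_factors[j] = np.sum(m[sel] * w[sel]) / np.sum(w[sel])
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def spearman_matrix(expression: pd.DataFrame, pairs: str = "all") -> pd.DataFrame:
    """Pairwise Spearman rank correlation between samples (columns).

    Uses average ranks for ties. Constant columns yield NaN entries with a
    warning. Diagonal is 1; the matrix is symmetric.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    cols = list(expression.columns)
    mat = expression.to_numpy(dtype=float)
    constant = [c for j, c in enumerate(cols) if np.all(mat[:, j] == mat[0, j])]
    if constant:
        logger.warning("constant columns, correlations undefined: %s", constant)
    n = len(cols)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if cols[i] in constant or cols[j] in constant:
                rho = np.nan
            else:
                rho = stats.spearmanr(mat[:, i], mat[:, j]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=cols, columns=cols)


def leading_logfc_distances(
    normalized: pd.DataFrame,
    library_sizes: Optional[pd.Series] = None,
    factors: Optional[pd.Series] = None,
    counts: Optional[pd.DataFrame] = None,
    top_n: int = 500,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Pairwise sample distances: RMS of the top_n largest |log2 fold changes|.

    When raw ``counts`` are given, per-gene log-expression is
    log2((count + prior_count) / (libsize * factor)); otherwise
    log2(normalized + prior_count) is used.
    """
    if counts is not None:
        lib = counts.sum(axis=0).astype(float) if library_sizes is None else library_sizes
        f = pd.Series(1.0, index=counts.columns) if factors is None else factors
        logexp = np.log2(counts.add(prior_count)) - np.log2(lib * f)
    else:
        logexp = np.log2(normalized + prior_count)
    cols = list(logexp.columns)
    arr = logexp.to_numpy(dtype=float)
    n = len(cols)
    k = min(top_n, arr.shape[0])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lfc = np.abs(arr[:, i] - arr[:, j])
            top = np.sort(lfc)[-k:]
            d = float(np.sqrt(np.mean(top ** 2)))
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=cols, columns=cols)


def classical_mds(distances: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Coordinates are determined up to sign/rotation; signs are fixed so the
    largest-magnitude loading of each axis is positive.
    """
    n = distances.shape[0]
    if dims >= n:
        raise ValueError(f"dims ({dims}) must be < number of samples ({n})")
    d2 = distances.to_numpy(dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, dims))
    for k in range(dims):
        lam = max(evals[k], 0.0)
        v = evecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, k] = v * np.sqrt(lam)
    return pd.DataFrame(
        coords, index=distances.index, columns=[f"dim{k+1}" for k in range(dims)]
    )


def mds_coordinates(
    normalized: pd.DataFrame,
    top_n: int = 500,
    dims: int = 2,
    **dist_kwargs,
) -> pd.DataFrame:
    """Leading-logFC distances followed by classical MDS."""
    if normalized.shape[1] <= dims:
        raise ValueError("need more samples than dimensions")
    dist = leading_logfc_distances(normalized, top_n=top_n, **dist_kwargs)
    return classical_mds(dist, dims=dims)
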