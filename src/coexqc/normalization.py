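"""Between-sample normalization of RNA-seq count matrices.

Six procedures are implemented, all operating on a genes x samples count
matrix and returning an :class:`~coexqc.data.ExpressionMatrix`:

``CPM``
    counts scaled to reads per million of the sample's total.
``UQ`` / ``Med``
    counts scaled by the upper quartile / median of the sample's
    *non-zero* counts (linear-interpolation quantiles).
``Quantile``
    every sample forced to the same empirical distribution: each column's
    sorted values are replaced by the across-sample mean of sorted values,
    tied ranks receiving the mean of the values they replace.
``TMM``
    trimmed mean of M-values: a per-sample scaling factor from the
    weighted, doubly-trimmed mean of gene-wise log ratios against a
    reference sample, applied on top of CPM scaling.  Genes below 1 CPM in
    every sample are removed first.
``Rlog``
    a simplified regularized log: median-of-ratios size factors, then a
    per-gene shrinkage of log2(count/s + 0.5) toward the gene's across-
    sample mean with weight m/(m + c) where m is the gene's mean
    normalized count — low-count genes are pulled toward their average,
    high-count genes approach a plain log transform.

Rlog output is already on the log2 scale and is flagged ``is_log``;
every other method's output goes through :func:`log_transform`, which adds
a pseudocount equal to the 1st percentile of the pooled non-zero
normalized values before taking log2.

Length-dependent normalizations (RPKM/FPKM) are deliberately absent: a
per-gene constant factor cannot change gene-gene correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountDataset, ExpressionMatrix

__all__ = ["normalize", "log_transform", "tmm_factors", "NORMALIZATION_METHODS"]

NORMALIZATION_METHODS = ("TMM", "CPM", "UQ", "Med", "Rlog", "Quantile")

_CANON = {m.lower(): m for m in NORMALIZATION_METHODS}


def _as_counts(data: CountDataset | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, CountDataset):
        return data.counts
    return data


def normalize(data: CountDataset | pd.DataFrame, method: str) -> ExpressionMatrix:
    """Apply one of the six normalization methods.

    Parameters
    ----------
    data
        Count dataset or raw genes x samples count DataFrame.
    method
        One of ``TMM, CPM, UQ, Med, Rlog, Quantile`` (case-insensitive).
    """
    counts = _as_counts(data)
    key = _CANON.get(str(method).lower())
    if key is None:
        raise ValueError(f"unknown normalization method: {method!r}")
    values, is_log = _DISPATCH[key](counts)
    return ExpressionMatrix(values, provenance=[f"normalize:{key}"], is_log=is_log)


def _cpm(counts: pd.DataFrame):
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total count: {bad[:5]}")
    return counts * (1e6 / totals), False


def _nonzero_quantile_divisors(counts: pd.DataFrame, q: float, label: str) -> pd.Series:
    divisors = {}
    for s in counts.columns:
        col = counts[s].to_numpy()
        nz = col[col != 0]
        if nz.size == 0:
            raise ValueError(f"{label} normalization: sample {s!r} has only zero counts")
        divisors[s] = np.percentile(nz, q)  # linear interpolation between order stats
    return pd.Series(divisors)


def _uq(counts: pd.DataFrame):
    div = _nonzero_quantile_divisors(counts, 75, "UQ")
    return counts / div, False


def _med(counts: pd.DataFrame):
    div = _nonzero_quantile_divisors(counts, 50, "Med")
    return counts / div, False


def _quantile(counts: pd.DataFrame):
    x = counts.to_numpy(dtype=float)
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = mean_sorted
        # tied input values receive the mean of the values they replaced
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        cnts = np.bincount(inverse)
        out[:, j] = (sums / cnts)[inverse]
    return pd.DataFrame(out, index=counts.index, columns=counts.columns), False


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                sum_trim: float = 0.05, do_weighting: bool = True) -> pd.Series:
    """Per-sample TMM scaling factors (edgeR-default algorithm).

    The reference sample is the one whose library-size-scaled 75th
    percentile is closest to the mean across samples.  For every other
    sample, gene-wise log2 ratios M and average log2 abundances A are
    computed against the reference (genes zero in either sample dropped);
    the 30% most extreme M and 5% most extreme A are trimmed two-sided,
    and the remaining M are averaged with inverse asymptotic binomial
    variance weights.  Factors are rescaled to have geometric mean 1.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("TMM: sample with zero total count")
    f75 = np.percentile(x, 75, axis=0) / lib
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = x[:, ref_j]
    nR = lib[ref_j]

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        obs = x[:, j]
        nO = lib[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            logR = np.log2((obs / nO) / (ref / nR))
            absE = (np.log2(obs / nO) + np.log2(ref / nR)) / 2.0
            v = (nO - obs) / (nO * obs) + (nR - ref) / (nR * ref)
        keep = np.isfinite(logR) & np.isfinite(absE)
        logR, absE, v = logR[keep], absE[keep], v[keep]
        if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
            continue
        n = logR.size
        loL = np.floor(n * logratio_trim) + 1
        hiL = n + 1 - loL
        loS = np.floor(n * sum_trim) + 1
        hiS = n + 1 - loS
        rR = stats.rankdata(logR)
        rA = stats.rankdata(absE)
        kept = (rR >= loL) & (rR <= hiL) & (rA >= loS) & (rA <= hiS)
        if not kept.any():
            continue
        if do_weighting:
            f = np.sum(logR[kept] / v[kept]) / np.sum(1.0 / v[kept])
        else:
            f = np.mean(logR[kept])
        if np.isfinite(f):
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def _tmm(counts: pd.DataFrame):
    # pre-filter: drop genes with < 1 CPM in every sample
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"samples with zero total count: {bad[:5]}")
    cpm = counts * (1e6 / lib)
    kept = counts.loc[(cpm >= 1).any(axis=1)]
    if kept.shape[0] == 0:
        raise ValueError("TMM: no gene reaches 1 CPM in any sample")
    # library sizes and factors on the filtered matrix, as edgeR does
    kept_lib = kept.sum(axis=0)
    factors = tmm_factors(kept)
    values = kept * (1e6 / kept_lib) / factors
    return values, False


def _rlog(counts: pd.DataFrame, shrink_c: float = 10.0):
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    log_geomeans = logx.mean(axis=1)  # -inf for genes with any zero
    finite = np.isfinite(log_geomeans)
    if not finite.any():
        raise ValueError("Rlog: no gene has non-zero counts in every sample")
    ratios = logx[finite] - log_geomeans[finite, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    norm = x / size_factors[None, :]
    v = np.log2(norm + 0.5)
    mu = v.mean(axis=1, keepdims=True)
    mbar = norm.mean(axis=1, keepdims=True)
    w = mbar / (mbar + shrink_c)
    out = mu + w * (v - mu)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns), True


_DISPATCH = {
    "CPM": _cpm,
    "UQ": _uq,
    "Med": _med,
    "Quantile": _quantile,
    "TMM": _tmm,
    "Rlog": _rlog,
}


def log_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """log2 with a data-driven pseudocount.

    The pseudocount is the 1st percentile of the pooled non-zero values
    of the whole normalized matrix; it is recorded in the provenance.
    Refuses matrices already on a log scale (e.g. Rlog output).
    """
    if mat.is_log:
        raise ValueError("matrix is already on a log scale")
    vals = mat.values.to_numpy(dtype=float)
    nz = vals[vals != 0]
    if nz.size == 0:
        raise ValueError("cannot log-transform an all-zero matrix")
    p = float(np.percentile(nz, 1))
    out = pd.DataFrame(np.log2(vals + p), index=mat.values.index, columns=mat.values.columns)
    return mat.with_values(out, f"log2(pseudocount={p:.6g})", pseudocount=p, is_log=True)
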