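"""Batch (study) effect removal from log-scale expression.

Two correctors are provided, both protecting biological covariates:

``remove_batch_linear``
    per-gene ordinary least squares on biology indicators plus
    sum-to-zero batch contrasts; the fitted batch component is subtracted,
    leaving the grand level and biology-attributable variation intact.

``combat``
    parametric empirical-Bayes location/scale adjustment: per-gene batch
    location (gamma) and scale (delta^2) estimates are shrunk toward
    moment-matched batch-level priors (normal for gamma, inverse-gamma for
    delta^2) through the standard fixed-point iteration, then the
    standardized data are adjusted and rescaled.

Correction is only meaningful where batches share biology.  Samples are
first partitioned into *confounding blocks* — connected components of the
bipartite batch-biology graph — and each block is corrected separately
and merged back.  Blocks containing a single batch are passed through
unchanged, as are blocks where batch is completely aliased with biology
(with a warning): removing "batch" there would remove the biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .data import ExpressionMatrix

__all__ = [
    "BatchDesign",
    "ConfoundingBlock",
    "EBBatchModel",
    "partition_confounding_blocks",
    "remove_batch_linear",
    "combat",
    "correct_batches",
]


@dataclass
class BatchDesign:
    """Per-sample batch and biology labels."""

    batch_of: pd.Series
    biology_of: pd.Series

    def __post_init__(self) -> None:
        self.batch_of = pd.Series(self.batch_of)
        self.biology_of = pd.Series(self.biology_of)
        if len(self.batch_of) == 0:
            raise ValueError("empty batch design")
        if set(self.batch_of.index) != set(self.biology_of.index):
            raise ValueError("batch and biology labels cover different samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.batch_of.index)

    def subset(self, samples: list[str]) -> "BatchDesign":
        return BatchDesign(self.batch_of.loc[samples], self.biology_of.loc[samples])


@dataclass
class ConfoundingBlock:
    """A connected component of the batch-biology bipartite graph."""

    samples: list[str]
    batches: set[str]
    biologies: set[str]

    @property
    def correctable(self) -> bool:
        return len(self.batches) > 1


@dataclass
class EBBatchModel:
    """ComBat model parameters for one confounding block.

    Raw (``gamma_hat``, ``delta2_hat``) and EB-shrunken (``gamma_star``,
    ``delta2_star``) per-batch per-gene location/scale estimates, plus the
    per-batch moment-matched hyperpriors.
    """

    batches: list[str]
    gamma_hat: np.ndarray      # (n_batches, n_genes)
    delta2_hat: np.ndarray
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    gamma_prior: list[tuple[float, float]] = field(default_factory=list)   # (mean, var)
    delta2_prior: list[tuple[float, float]] = field(default_factory=list)  # (shape, scale)
    n_iterations: list[int] = field(default_factory=list)


def partition_confounding_blocks(design: BatchDesign) -> list[ConfoundingBlock]:
    """Split samples into independently correctable subsets.

    Two batches fall in the same block when a chain of shared biologies
    connects them; correction inside a block can then distinguish batch
    from biology.  Single-batch blocks are flagged uncorrectable.
    """
    batches = sorted(set(design.batch_of), key=str)
    biologies = sorted(set(design.biology_of), key=str)
    b_index = {b: i for i, b in enumerate(batches)}
    y_index = {y: len(batches) + i for i, y in enumerate(biologies)}
    n = len(batches) + len(biologies)
    rows, cols = [], []
    for s in design.sample_ids:
        i, j = b_index[design.batch_of[s]], y_index[design.biology_of[s]]
        rows += [i, j]
        cols += [j, i]
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    blocks: dict[int, ConfoundingBlock] = {}
    for s in design.sample_ids:
        comp = labels[b_index[design.batch_of[s]]]
        blk = blocks.setdefault(comp, ConfoundingBlock([], set(), set()))
        blk.samples.append(s)
        blk.batches.add(design.batch_of[s])
        blk.biologies.add(design.biology_of[s])
    return [blocks[c] for c in sorted(blocks)]


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(set(labels), key=str)
    mat = np.column_stack([(labels == lv).astype(float) for lv in levels])
    return mat, levels


def _sum_to_zero(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """n x (B-1) sum-to-zero batch contrasts (last level = -1 row)."""
    levels = sorted(set(labels), key=str)
    B = len(levels)
    mat = np.zeros((len(labels), B - 1))
    for i, lv in enumerate(levels[:-1]):
        mat[labels == lv, i] = 1.0
    mat[labels == levels[-1], :] = -1.0
    return mat, levels


def _block_linear(values: np.ndarray, batch: np.ndarray, biology: np.ndarray) -> np.ndarray | None:
    """Per-gene OLS batch-component removal; None if batch aliased with biology."""
    x_bio, _ = _one_hot(biology)
    x_batch, _ = _sum_to_zero(batch)
    X = np.hstack([x_bio, x_batch])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    batch_part = x_batch @ beta[x_bio.shape[1]:, :]
    return values - batch_part.T


def _block_combat(
    values: np.ndarray,
    batch: np.ndarray,
    biology: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, EBBatchModel]:
    batch_levels = sorted(set(batch), key=str)
    n_batch = len(batch_levels)
    n = len(batch)
    batch_idx = [np.flatnonzero(batch == b) for b in batch_levels]
    for b, idx in zip(batch_levels, batch_idx):
        if idx.size < 2:
            raise ValueError(f"batch {b!r} has a single sample; ComBat needs >= 2 per batch")

    x_batch = np.column_stack([(batch == b).astype(float) for b in batch_levels])
    bio_levels = sorted(set(biology), key=str)
    x_bio = np.column_stack([(biology == lv).astype(float) for lv in bio_levels[1:]]) \
        if len(bio_levels) > 1 else np.empty((n, 0))
    X = np.hstack([x_batch, x_bio])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch aliased with biology inside a block; cannot fit ComBat model")

    beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)  # (p, n_genes)
    fitted = (X @ beta).T
    resid = values - fitted
    var_pooled = (resid ** 2).mean(axis=1)  # per gene, 1/n as in the reference
    if (var_pooled <= 0).any():
        raise ValueError("gene with zero pooled variance; filter constant genes first")

    batch_prop = np.array([idx.size / n for idx in batch_idx])
    grand_mean = batch_prop @ beta[:n_batch, :]
    stand_mean = grand_mean[:, None] + (x_bio @ beta[n_batch:, :]).T
    sd = np.sqrt(var_pooled)[:, None]
    Z = (values - stand_mean) / sd

    gamma_hat = np.vstack([Z[:, idx].mean(axis=1) for idx in batch_idx])
    delta2_hat = np.vstack([Z[:, idx].var(axis=1, ddof=1) for idx in batch_idx])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    gamma_prior, delta2_prior, n_iters = [], [], []
    for i, idx in enumerate(batch_idx):
        g_hat, d_hat = gamma_hat[i], delta2_hat[i]
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a = (2 * s2 + m ** 2) / s2
        b = (m * s2 + m ** 3) / s2
        n_i = idx.size
        g_old, d_old = g_hat.copy(), d_hat.copy()
        converged = False
        for it in range(1, max_iter + 1):
            g_new = (n_i * t2 * g_hat + d_old * g_bar) / (n_i * t2 + d_old)
            sum2 = ((Z[:, idx] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b) / (n_i / 2.0 + a - 1.0)
            change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
            g_old, d_old = g_new, d_new
            if change < tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"ComBat EB iteration did not converge for batch {batch_levels[i]!r} "
                f"after {max_iter} iterations (last change {change:.3g})"
            )
        gamma_star[i], delta2_star[i] = g_old, d_old
        gamma_prior.append((float(g_bar), float(t2)))
        delta2_prior.append((float(a), float(b)))
        n_iters.append(it)

    adjusted = Z.copy()
    for i, idx in enumerate(batch_idx):
        adjusted[:, idx] = (Z[:, idx] - gamma_star[i][:, None]) / np.sqrt(delta2_star[i])[:, None]
    adjusted = adjusted * sd + stand_mean

    model = EBBatchModel(
        batches=[str(b) for b in batch_levels],
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_prior=gamma_prior,
        delta2_prior=delta2_prior,
        n_iterations=n_iters,
    )
    return adjusted, model


def _apply_per_block(mat: ExpressionMatrix, design: BatchDesign, corrector, step: str,
                     collect_models: list | None = None) -> ExpressionMatrix:
    if not mat.is_log:
        raise ValueError("batch correction expects log-scale expression")
    samples = mat.sample_ids
    design = design.subset(samples)
    out = mat.values.to_numpy(dtype=float).copy()
    col_of = {s: j for j, s in enumerate(samples)}
    for block in partition_confounding_blocks(design):
        cols = np.array([col_of[s] for s in block.samples])
        if not block.correctable:
            continue  # single batch: merged back unchanged
        batch = design.batch_of.loc[block.samples].to_numpy()
        biology = design.biology_of.loc[block.samples].to_numpy()
        result = corrector(out[:, cols], batch, biology)
        if result is None:
            warnings.warn(
                f"batch aliased with biology in block {sorted(map(str, block.batches))}; "
                "block left uncorrected",
                stacklevel=3,
            )
            continue
        if isinstance(result, tuple):
            result, model = result
            if collect_models is not None:
                collect_models.append(model)
        out[:, cols] = result
    values = pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    return mat.with_values(values, step)


def remove_batch_linear(mat: ExpressionMatrix, design: BatchDesign) -> ExpressionMatrix:
    """OLS removal of batch effects, preserving biology group means."""
    return _apply_per_block(mat, design, _block_linear, "correct:linear")


def combat(mat: ExpressionMatrix, design: BatchDesign,
           models: list[EBBatchModel] | None = None,
           tol: float = 1e-6, max_iter: int = 500) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch adjustment (ComBat algorithm).

    Pass a list as *models* to collect the fitted :class:`EBBatchModel`
    of every corrected block.
    """
    def corrector(values, batch, biology):
        try:
            return _block_combat(values, batch, biology, tol=tol, max_iter=max_iter)
        except ValueError as err:
            if "aliased" in str(err):
                return None
            raise

    return _apply_per_block(mat, design, corrector, "correct:combat", collect_models=models)


def correct_batches(mat: ExpressionMatrix, design: BatchDesign, method: str) -> ExpressionMatrix:
    """Dispatch on ``method`` in {none, linear, combat}."""
    method = str(method).lower()
    if method == "none":
        return mat.with_values(mat.values.copy(), "correct:none")
    if method == "linear":
        return remove_batch_linear(mat, design)
    if method == "combat":
        return combat(mat, design)
    raise ValueError(f"unknown batch correction method: {method!r}")
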