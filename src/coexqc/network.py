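"""Gene filtering, correlation, and top-K neighbor extraction.

A co-expression network here is, for every gene X, the ordered set of the
K genes most correlated with X (``set_X``, K = 100 by default, X itself
excluded).  Ties are broken deterministically: descending correlation,
then ascending gene identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountDataset, ExpressionMatrix

__all__ = [
    "filter_genes",
    "correlation_matrix",
    "top_k_neighbors",
    "CoexpressionNetwork",
]


def filter_genes(data: CountDataset | pd.DataFrame) -> list[str]:
    """Genes passing the low-expression and zero-variance filters.

    Operating on *raw counts*, a gene is removed when any of:

    * fewer than 10 reads in more than 90% of samples;
    * fewer than 10 reads in more than 80% of samples and never 50 or
      more reads in any sample;
    * zero standard deviation across samples.

    The fractions use strict inequalities, so a gene sitting exactly on
    a boundary is retained.
    """
    counts = data.counts if isinstance(data, CountDataset) else data
    x = counts.to_numpy(dtype=float)
    frac_low = (x < 10).mean(axis=1)
    max_count = x.max(axis=1)
    sd = x.std(axis=1)
    removed = (frac_low > 0.9) | ((frac_low > 0.8) & (max_count < 50)) | (sd == 0)
    return list(counts.index[~removed])


def correlation_matrix(
    mat: ExpressionMatrix | pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Gene-gene correlation of a genes x samples matrix.

    ``pearson`` is the product-moment correlation; ``spearman`` is
    Pearson on per-gene mid-ranks (ties get their average rank).
    Constant genes must have been filtered out beforehand.
    """
    values = mat.values if isinstance(mat, ExpressionMatrix) else mat
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlation")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])
        raise ValueError(f"constant genes must be filtered before correlation: {bad[:5]}")
    method = str(method).lower()
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method: {method!r}")
    cor = np.corrcoef(x)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=values.index, columns=values.index)


@dataclass
class CoexpressionNetwork:
    """Top-K neighbor sets of every gene, with the workflow that made them.

    ``neighbors[i, r]`` is the index (into ``gene_ids``) of the rank-r+1
    neighbor of gene i; ``neighbor_corr`` holds the matching correlations.
    """

    gene_ids: list[str]
    neighbors: np.ndarray
    neighbor_corr: np.ndarray
    correlation_method: str
    k: int
    workflow: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def neighbor_sets(self) -> dict[str, list[str]]:
        """gene X -> ordered list of neighbor gene ids (set_X)."""
        ids = np.asarray(self.gene_ids, dtype=object)
        return {g: list(ids[self.neighbors[i]]) for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.gene_ids, dtype=object)
        n, k = self.neighbors.shape
        return pd.DataFrame(
            {
                "gene_id": np.repeat(ids, k),
                "rank": np.tile(np.arange(1, k + 1), n),
                "neighbor_id": ids[self.neighbors.ravel()],
                "correlation": self.neighbor_corr.ravel(),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, correlation_method: str = "",
                   workflow: dict | None = None) -> "CoexpressionNetwork":
        gene_ids = list(dict.fromkeys(frame["gene_id"]))
        index = {g: i for i, g in enumerate(gene_ids)}
        k = int(frame["rank"].max())
        n = len(gene_ids)
        neighbors = np.empty((n, k), dtype=int)
        corr = np.empty((n, k))
        for g, sub in frame.groupby("gene_id", sort=False):
            sub = sub.sort_values("rank")
            neighbors[index[g]] = [index[x] for x in sub["neighbor_id"]]
            corr[index[g]] = sub["correlation"].to_numpy()
        return cls(gene_ids, neighbors, corr, correlation_method, k, workflow or {})

    @classmethod
    def read(cls, path: str | Path, **kwargs) -> "CoexpressionNetwork":
        return cls.from_frame(pd.read_csv(path, sep="\t"), **kwargs)


def top_k_neighbors(
    cor: pd.DataFrame, k: int = 100, correlation_method: str = "",
    workflow: dict | None = None,
) -> CoexpressionNetwork:
    """Extract each gene's K most correlated genes (self excluded).

    Requires ``k < n_genes``.  Ties are resolved by ascending gene
    identifier, making the result bit-reproducible.
    """
    n = cor.shape[0]
    if cor.shape[0] != cor.shape[1]:
        raise ValueError("correlation matrix must be square")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of genes ({n})")
    if k < 1:
        raise ValueError("k must be positive")
    gene_ids = list(cor.index)
    c = cor.to_numpy(dtype=float)

    # Reorder columns by ascending gene id so that a stable sort on
    # descending correlation breaks ties by identifier.
    id_order = np.argsort(np.asarray(gene_ids, dtype=object), kind="stable")
    c_sorted = c[:, id_order]
    order = np.argsort(-c_sorted, axis=1, kind="stable")
    cols = id_order[order]  # (n, n) original column indices, best first

    # Self sits somewhere in each row's first k+1 entries unless crowded out
    # by >k ties, in which case the first k entries are already correct.
    cand = cols[:, : k + 1]
    not_self = cand != np.arange(n)[:, None]
    first_k = np.argsort(~not_self, axis=1, kind="stable")[:, :k]
    first_k.sort(axis=1)  # keep correlation order among the selected
    neighbors = np.take_along_axis(cand, first_k, axis=1)
    neighbor_corr = np.take_along_axis(c, neighbors, axis=1)
    return CoexpressionNetwork(
        gene_ids=gene_ids,
        neighbors=neighbors,
        neighbor_corr=neighbor_corr,
        correlation_method=correlation_method,
        k=k,
        workflow=workflow or {},
    )
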