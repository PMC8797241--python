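"""Enrichment-based quality measures for co-expression networks.

Eight measures, two per annotation domain (GO Molecular Function,
Biological Process, Cellular Component, and promoter TFBS motifs):

* ``Enrichment_d`` — the fraction of network genes X whose ``set_X``
  (top-K correlated genes) contains at least one significantly enriched
  term of domain d.
* ``Accuracy_d`` — the fraction of network genes X whose *own*
  annotations of domain d intersect the terms enriched in ``set_X``.

Enrichment per term uses the one-sided hypergeometric tail over the
network's gene universe, with Benjamini-Hochberg control across the
tested terms of a domain within each ``set_X`` (alpha 0.05 by default).
Terms with fewer than ``min_term_size`` genes in the universe, or
covering more than half of it, are not tested.

Accuracy can never exceed the matching Enrichment: a gene counted for
accuracy necessarily has at least one enriched term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import CoexpressionNetwork

__all__ = [
    "AnnotationDomainSets",
    "QualityMeasures",
    "MEASURE_COLUMNS",
    "enriched_terms",
    "network_quality_measures",
    "bh_adjust",
]

#: Canonical column order of the eight quality measures.
MEASURE_COLUMNS = [
    "enrichment_mf",
    "enrichment_bp",
    "enrichment_cc",
    "enrichment_tfbs",
    "accuracy_mf",
    "accuracy_bp",
    "accuracy_cc",
    "accuracy_tfbs",
]


@dataclass
class AnnotationDomainSets:
    """Term -> gene-set annotations of one domain (MF/BP/CC/TFBS)."""

    domain: str
    term_to_genes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.term_to_genes = {t: frozenset(g) for t, g in self.term_to_genes.items()}

    @property
    def gene_to_terms(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for term, genes in self.term_to_genes.items():
            for g in genes:
                inv.setdefault(g, set()).add(term)
        return inv

    def restricted_to(
        self, universe: set[str], min_term_size: int = 5, max_frac: float = 0.5
    ) -> "AnnotationDomainSets":
        """Intersect term sets with *universe*; drop untestable terms.

        Terms keeping fewer than *min_term_size* genes, or more than
        ``max_frac`` of the universe, are excluded from testing.
        """
        universe = set(universe)
        max_size = max_frac * len(universe)
        kept = {}
        for term, genes in self.term_to_genes.items():
            inter = genes & universe
            if min_term_size <= len(inter) <= max_size:
                kept[term] = frozenset(inter)
        return AnnotationDomainSets(self.domain, kept)


@dataclass
class QualityMeasures:
    """The eight quality fractions of one network."""

    enrichment: dict[str, float]
    accuracy: dict[str, float]
    n_genes: int
    n_terms_tested: dict[str, int] = field(default_factory=dict)

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for d in self.enrichment:
            row[f"enrichment_{d.lower()}"] = self.enrichment[d]
        for d in self.accuracy:
            row[f"accuracy_{d.lower()}"] = self.accuracy[d]
        row["n_genes"] = self.n_genes
        for d, n in self.n_terms_tested.items():
            row[f"n_terms_{d.lower()}"] = n
        return row


def bh_adjust(p: np.ndarray, axis: int = 0) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values along *axis* (vectorized).

    Matches ``statsmodels.multipletests(method="fdr_bh")`` exactly; the
    in-package version exists because the network measures adjust one
    small p-vector per gene across thousands of genes at once.
    """
    p = np.asarray(p, dtype=float)
    p = np.moveaxis(p, axis, -1)
    m = p.shape[-1]
    order = np.argsort(p, axis=-1)
    ranked = np.take_along_axis(p, order, axis=-1)
    adj = ranked * (m / np.arange(1, m + 1))
    adj = np.minimum.accumulate(adj[..., ::-1], axis=-1)[..., ::-1]
    out = np.empty_like(adj)
    np.put_along_axis(out, order, np.minimum(adj, 1.0), axis=-1)
    return np.moveaxis(out, -1, axis)


def enriched_terms(
    set_x: set[str],
    annots: AnnotationDomainSets,
    universe: set[str],
    alpha: float = 0.05,
) -> set[str]:
    """Terms of one domain significantly over-represented in ``set_x``.

    One-sided hypergeometric tail P[overlap >= observed] with population
    size |universe|, then BH across the domain's tested terms; terms with
    adjusted p <= *alpha* are returned.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    set_x = set(set_x) & universe
    terms = list(annots.term_to_genes)
    if not terms:
        return set()
    N, n_draw = len(universe), len(set_x)
    pvals = []
    for term in terms:
        members = annots.term_to_genes[term] & universe
        overlap = len(members & set_x)
        pvals.append(stats.hypergeom.sf(overlap - 1, N, len(members), n_draw))
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return {t for t, r in zip(terms, reject) if r}


def _domain_fractions(
    net: CoexpressionNetwork,
    annots: AnnotationDomainSets,
    alpha: float,
) -> tuple[float, float, int]:
    """Vectorized Enrichment/Accuracy for one domain over all genes."""
    genes = net.gene_ids
    g_index = {g: i for i, g in enumerate(genes)}
    n, k = net.neighbors.shape
    terms = list(annots.term_to_genes)
    if not terms:
        return 0.0, 0.0, 0
    membership = np.zeros((len(terms), n), dtype=bool)
    for t_i, term in enumerate(terms):
        for g in annots.term_to_genes[term]:
            j = g_index.get(g)
            if j is not None:
                membership[t_i, j] = True

    # overlap[t, X] = |term_t  ∩  set_X|
    set_ind = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    set_ind[net.neighbors.ravel(), rows] = 1.0  # column X marks members of set_X
    overlap = membership.astype(float) @ set_ind

    term_sizes = membership.sum(axis=1)
    # p depends only on (term size, overlap); tabulate over overlap 0..k
    # instead of evaluating the tail per gene
    uniq_sizes, size_idx = np.unique(term_sizes, return_inverse=True)
    grid = np.arange(k + 1)
    table = stats.hypergeom.sf(grid[None, :] - 1, n, uniq_sizes[:, None], k)
    pvals = table[size_idx[:, None], overlap.astype(int)]
    padj = bh_adjust(pvals, axis=0)
    enr_mask = padj <= alpha  # (terms, genes)

    enrichment = float(enr_mask.any(axis=0).mean())
    accuracy = float((enr_mask & membership).any(axis=0).mean())
    return enrichment, accuracy, len(terms)


def network_quality_measures(
    net: CoexpressionNetwork,
    annotations: dict[str, AnnotationDomainSets] | dict[str, dict[str, set[str]]],
    alpha: float = 0.05,
    min_term_size: int = 5,
    max_term_frac: float = 0.5,
) -> QualityMeasures:
    """Compute the eight quality fractions of a network.

    *annotations* maps domain -> :class:`AnnotationDomainSets` (or a raw
    term -> gene-set dict).  The gene universe is the network's gene set;
    annotations are restricted to it before testing.
    """
    universe = set(net.gene_ids)
    enrichment: dict[str, float] = {}
    accuracy: dict[str, float] = {}
    n_terms: dict[str, int] = {}
    for domain, annots in annotations.items():
        if not isinstance(annots, AnnotationDomainSets):
            annots = AnnotationDomainSets(domain, annots)
        annots = annots.restricted_to(universe, min_term_size, max_term_frac)
        e, a, t = _domain_fractions(net, annots, alpha)
        enrichment[domain] = e
        accuracy[domain] = a
        n_terms[domain] = t
    return QualityMeasures(
        enrichment=enrichment,
        accuracy=accuracy,
        n_genes=net.n_genes,
        n_terms_tested=n_terms,
    )
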