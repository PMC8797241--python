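"""Synthetic multi-study RNA-seq count data with known co-expression modules.

The generator emulates the statistical structure the downstream pipeline
assumes in real compendia: negative-binomial counts with variable library
sizes, latent co-expression modules shared by annotated gene sets, and
per-batch (per-study) location and scale effects on the log scale.

The generative model, per gene ``g`` and sample ``s`` in batch ``b(s)``:

    log2 mean_{g,s} = b_g + L * a_{m(g),s} * [g in a module]
                      + gamma_{g,b(s)} + e_{g,s}

with module activities ``a_{m,s} ~ N(0,1)``, gene intercepts
``b_g ~ N(baseline_log_mean, baseline_log_sd^2)``, batch location shifts
``gamma_{g,b} ~ N(0, batch_loc_sd^2)``, and residual noise
``e_{g,s} ~ N(0, 0.25 * exp(delta_b))`` where ``delta_b ~ N(0,
batch_scale_sd^2)`` is a per-batch log variance-scale factor.  Counts are
negative binomial with mean ``l_s * 2^{log2 mean}`` (library factor
``l_s ~ LogNormal(0, libsize_log_sd)``) and variance ``mu + phi * mu^2``.

With the base residual variance 0.25, the within-module correlation of the
latent log expression is L^2 / (L^2 + 0.25): loadings L in [0.5, 2] span a
realistic 0.5-0.94 range.

Annotation sets mimic GO / promoter-motif gene sets: each module owns one
term per annotation domain, populated from the module's genes with a true
positive rate, plus background terms populated at a false positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountDataset, write_gmt, write_ground_truth_json

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_annotations",
    "DOMAINS",
]

#: The four annotation domains scored downstream: GO Molecular Function,
#: Biological Process, Cellular Component, and promoter TFBS motifs.
DOMAINS = ("MF", "BP", "CC", "TFBS")

#: Base residual variance on the log2 scale (see module docstring).
RESIDUAL_VARIANCE = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic count generator.

    Defaults give a mid-sized single-tissue dataset of the kind the
    benchmark runs on: 1,000 genes of which 200 sit in 10 co-expression
    modules, 100 samples from 4 studies, moderate overdispersion and
    batch effects.
    """

    n_genes: int = 1000
    n_samples: int = 100
    n_batches: int = 4
    n_modules: int = 10
    module_size: int = 20
    loading: float = 1.0            # module effect size L (log2 scale)
    baseline_log_mean: float = 5.0  # mean of per-gene log2 intercepts
    baseline_log_sd: float = 2.0
    nb_dispersion: float = 0.1      # phi in var = mu + phi mu^2; 0 -> Poisson
    batch_loc_sd: float = 0.5       # sd of per-gene per-batch log2 shifts
    batch_scale_sd: float = 0.2     # sd of per-batch log variance-scale factors
    libsize_log_sd: float = 0.3
    n_terms_per_domain: int = 30    # background (non-module) terms per domain
    annot_tpr: float = 0.8          # P(module gene carries its module's term)
    annot_fpr: float = 0.01         # P(any gene carries a background term)
    seed: int = 0
    # Artifact samples: `n_outlier_samples` samples per dataset (a fixed
    # count, emulating the rare technically aberrant libraries of real
    # compendia) carry extra per-gene noise of scale `outlier_noise_sd`
    # on the log2 scale.  With `outlier_noise_df` = inf the per-gene
    # deviations are Gaussian; finite values draw scaled Student-t
    # deviates, making the contamination itself heavy-tailed.  The
    # marginal expression distribution becomes heavy-tailed either way.
    n_outlier_samples: int = 0
    outlier_noise_sd: float = 0.0
    outlier_noise_df: float = float("inf")
    # Module activity tail: with `activity_df` = inf activities are
    # standard normal; finite values draw Student-t deviates rescaled to
    # unit variance (requires df > 2), emulating burst-like activation
    # where rare extreme samples carry real co-expression signal.
    activity_df: float = float("inf")

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_batches", "n_modules", "module_size", "n_terms_per_domain"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size exceeds n_genes")
        for name in ("annot_tpr", "annot_fpr"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("baseline_log_sd", "batch_loc_sd", "batch_scale_sd", "libsize_log_sd", "outlier_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.loading < 0:
            raise ValueError("loading must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def updated(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class GroundTruth:
    """True module membership and module-term identities of a simulation."""

    module_of_gene: dict[str, int | None]
    term_of_module: dict[str, dict[int, str]] = field(default_factory=dict)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == module]

    @property
    def modules(self) -> list[int]:
        return sorted({m for m in self.module_of_gene.values() if m is not None})

    def co_membership(self, a: str, b: str) -> bool:
        ma, mb = self.module_of_gene[a], self.module_of_gene[b]
        return ma is not None and ma == mb

    def write(self, path: str | Path) -> None:
        write_ground_truth_json(
            {"module_of_gene": self.module_of_gene, "term_of_module": self.term_of_module},
            path,
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion*mean^2); dispersion 0 -> Poisson."""
    # guard against overflow in exp-scale means for extreme parameter draws
    mean = np.minimum(mean, 1e9)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_dataset(
    config: SimulationConfig,
    biology: str = "tissue",
    biology_of_batch: list[str] | None = None,
    name: str | None = None,
    species: str = "human",
) -> tuple[CountDataset, GroundTruth]:
    """Simulate one count dataset; deterministic given ``config.seed``.

    Samples are assigned to batches round-robin (balanced).  By default
    every sample carries the single biology label *biology* (networks are
    built per cell type); passing ``biology_of_batch`` — one label per
    batch — produces a batch-confounded multi-biology design for
    exercising the confounding partitioner.
    """
    cfg = config
    if cfg.n_batches > cfg.n_samples:
        raise ValueError("n_batches cannot exceed n_samples")
    if biology_of_batch is not None and len(biology_of_batch) != cfg.n_batches:
        raise ValueError("biology_of_batch needs one label per batch")
    rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"s{i:04d}" for i in range(cfg.n_samples)]
    batch_idx = np.arange(cfg.n_samples) % cfg.n_batches
    batch_ids = [f"b{i:03d}" for i in range(cfg.n_batches)]

    module_of = np.full(cfg.n_genes, -1)
    for m in range(cfg.n_modules):
        module_of[m * cfg.module_size:(m + 1) * cfg.module_size] = m
    in_module = module_of >= 0

    if np.isinf(cfg.activity_df):
        activities = rng.normal(size=(cfg.n_modules, cfg.n_samples))
    else:
        if cfg.activity_df <= 2:
            raise ValueError("activity_df must exceed 2 (finite variance) or be inf")
        scale = np.sqrt(cfg.activity_df / (cfg.activity_df - 2.0))
        activities = rng.standard_t(cfg.activity_df, size=(cfg.n_modules, cfg.n_samples)) / scale
    intercepts = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    gamma = rng.normal(0.0, cfg.batch_loc_sd, size=(cfg.n_genes, cfg.n_batches))
    delta = rng.normal(0.0, cfg.batch_scale_sd, size=cfg.n_batches)
    resid_sd = np.sqrt(RESIDUAL_VARIANCE * np.exp(delta))[batch_idx]
    resid = rng.normal(size=(cfg.n_genes, cfg.n_samples)) * resid_sd

    log2mean = intercepts[:, None] + gamma[:, batch_idx] + resid
    log2mean[in_module] += cfg.loading * activities[module_of[in_module], :]

    if cfg.n_outlier_samples > 0 and cfg.outlier_noise_sd > 0:
        n_bad = min(cfg.n_outlier_samples, cfg.n_samples)
        bad = rng.choice(cfg.n_samples, size=n_bad, replace=False)
        if np.isinf(cfg.outlier_noise_df):
            deviates = rng.normal(size=(cfg.n_genes, n_bad))
        else:
            deviates = rng.standard_t(cfg.outlier_noise_df, size=(cfg.n_genes, n_bad))
        log2mean[:, bad] += cfg.outlier_noise_sd * deviates

    libsize = rng.lognormal(0.0, cfg.libsize_log_sd, size=cfg.n_samples) if cfg.libsize_log_sd > 0 else np.ones(cfg.n_samples)
    mean = libsize[None, :] * np.exp2(log2mean)
    counts = _nb_counts(rng, mean, cfg.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    if biology_of_batch is None:
        bio = pd.Series(biology, index=sample_ids)
    else:
        bio = pd.Series(np.asarray(biology_of_batch, dtype=object)[batch_idx], index=sample_ids)
    batch = pd.Series(np.asarray(batch_ids, dtype=object)[batch_idx], index=sample_ids)

    truth = GroundTruth(
        module_of_gene={g: (int(m) if m >= 0 else None) for g, m in zip(gene_ids, module_of)},
        term_of_module={
            d: {m: f"{d}:module{m:03d}" for m in range(cfg.n_modules)} for d in DOMAINS
        },
    )
    dataset = CountDataset(
        counts=counts_df,
        batch_of=batch,
        biology_of=bio,
        name=name if name is not None else f"sim_seed{cfg.seed}",
        species=species,
    )
    return dataset, truth


def generate_annotations(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, dict[str, set[str]]]:
    """Generate term -> gene-set maps for the four annotation domains.

    Each module's term draws the module's genes independently with
    probability ``annot_tpr``; each of ``n_terms_per_domain`` background
    terms draws every gene with probability ``annot_fpr``.  Serializable
    with :func:`coexqc.data.write_gmt`.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 7])
    genes = list(truth.module_of_gene)
    gene_arr = np.asarray(genes, dtype=object)
    annotations: dict[str, dict[str, set[str]]] = {}
    for domain in DOMAINS:
        term_sets: dict[str, set[str]] = {}
        for m, term in truth.term_of_module.get(domain, {}).items():
            members = truth.module_genes(m)
            keep = rng.random(len(members)) < cfg.annot_tpr
            term_sets[term] = {g for g, k in zip(members, keep) if k}
        for j in range(cfg.n_terms_per_domain):
            keep = rng.random(len(genes)) < cfg.annot_fpr
            term_sets[f"{domain}:bg{j:03d}"] = set(gene_arr[keep])
        annotations[domain] = term_sets
    return annotations


def write_simulation(
    outdir: str | Path,
    dataset: CountDataset,
    truth: GroundTruth,
    annotations: dict[str, dict[str, set[str]]],
) -> None:
    """Write counts/metadata TSVs, one GMT per domain, ground-truth JSON."""
    outdir = Path(outdir)
    dataset.write(outdir)
    for domain, sets in annotations.items():
        write_gmt(sets, outdir / f"annotations_{domain}.gmt")
    truth.write(outdir / "ground_truth.json")
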