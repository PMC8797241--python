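"""Workflow grid execution and regression analysis of network Quality.

A *workflow* is a (normalization, batch correction, correlation) triple.
The benchmark design crosses 6 normalizations with 4 correction options
(none, linear removal, ComBat, ComBat-seq) plus ComBat-seq applied to raw
counts without normalization — 25 processing combinations — and 2
correlation measures, i.e. 50 workflows.  ComBat-seq variants are
enumerable for design arithmetic but not executable here; the executable
subset is 6 x 3 x 2 = 36.

Each dataset x workflow cell yields one network and its eight quality
measures; :func:`coexqc.scoring.combine_quality` turns the collection
into Quality scores, which are then modeled by ordinary least squares on
log10 sample count, log10 batch count, species, and workflow dummies.
A coefficient beta is converted into the equivalent percent change in
sample count as ``100 * (10^(beta/beta_n) - 1)`` where ``beta_n`` is the
log10-sample-count slope: the processing choice buys the same Quality as
that many percent more samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .batch import BatchDesign, correct_batches
from .data import CountDataset
from .enrichment import MEASURE_COLUMNS, AnnotationDomainSets, network_quality_measures
from .network import correlation_matrix, filter_genes, top_k_neighbors
from .normalization import NORMALIZATION_METHODS, log_transform, normalize
from .scoring import QualityScoreTable, combine_quality

logger = logging.getLogger(__name__)

__all__ = [
    "WorkflowSpec",
    "QualityModel",
    "enumerate_workflows",
    "run_workflow",
    "run_workflow_grid",
    "split_train_validation",
    "fit_quality_model",
    "equivalent_sample_change",
    "cross_validate",
    "rank_workflows",
    "compare_workflows_paired",
    "REFERENCE_COEFFICIENTS",
]

CORRECTIONS = ("none", "linear", "combat", "combatseq")
CORRELATIONS = ("pearson", "spearman")

#: Published coefficients of the Quality regression from a large-scale
#: benchmark of 144 human and mouse cell-type/tissue compendia (3,888
#: training networks; baselines: Quantile normalization, no correction,
#: Pearson correlation, human).  Used as reference inputs for the
#: worked-example sample-equivalence conversions.
REFERENCE_COEFFICIENTS = pd.Series(
    {
        "intercept": -0.150,
        "log10_samples": 0.2894,
        "log10_batches": -0.0302,
        "species_mouse": 0.0462,
        "normalization_Rlog": 0.0231,
        "normalization_CPM": 0.0318,
        "normalization_TMM": 0.0540,
        "normalization_Med": 0.0638,
        "normalization_UQ": 0.0782,
        "correction_linear": 0.0412,
        "correction_combat": 0.0468,
        "correlation_spearman": -0.0107,
    },
    name="estimate",
)


@dataclass(frozen=True)
class WorkflowSpec:
    """One processing workflow: normalization + correction + correlation."""

    normalization: str
    correction: str
    correlation: str

    def __post_init__(self) -> None:
        if self.correction not in CORRECTIONS:
            raise ValueError(f"unknown correction: {self.correction!r}")
        if self.correlation not in CORRELATIONS:
            raise ValueError(f"unknown correlation: {self.correlation!r}")
        if self.normalization == "none":
            if self.correction != "combatseq":
                raise ValueError("normalization 'none' is only valid with combatseq")
        elif self.normalization not in NORMALIZATION_METHODS:
            raise ValueError(f"unknown normalization: {self.normalization!r}")

    @property
    def executable(self) -> bool:
        return self.correction != "combatseq"

    @property
    def name(self) -> str:
        return f"{self.normalization}+{self.correction}+{self.correlation}"


def enumerate_workflows(executable_only: bool = False) -> list[WorkflowSpec]:
    """The benchmark's 50 workflows (or the 36 executable ones).

    6 normalizations x 4 corrections plus ComBat-seq on raw counts,
    each with Pearson and Spearman correlation.  ComBat-seq workflows
    (an external count-scale corrector) are enumerable but not
    executable by this package.
    """
    specs = []
    for correlation in CORRELATIONS:
        for norm in NORMALIZATION_METHODS:
            for corr in CORRECTIONS:
                specs.append(WorkflowSpec(norm, corr, correlation))
        specs.append(WorkflowSpec("none", "combatseq", correlation))
    if executable_only:
        specs = [s for s in specs if s.executable]
    return specs


def run_workflow(
    dataset: CountDataset,
    spec: WorkflowSpec,
    annotations: dict[str, AnnotationDomainSets],
    k: int = 100,
    alpha: float = 0.05,
    min_term_size: int = 5,
) -> dict:
    """Run one dataset through one workflow; returns a measure-table row.

    Pipeline: normalize -> pseudocount log -> batch-correct -> gene
    filter -> correlation -> top-K neighbor sets -> eight measures.
    """
    if not spec.executable:
        raise ValueError(f"workflow {spec.name} is not executable (ComBat-seq out of scope)")
    retained = filter_genes(dataset)
    mat = normalize(dataset, spec.normalization)
    if not mat.is_log:
        mat = log_transform(mat)
    if spec.correction != "none":
        design = BatchDesign(dataset.batch_of, dataset.biology_of)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = correct_batches(mat, design, spec.correction)
    retained_set = set(retained)
    genes = [g for g in mat.gene_ids if g in retained_set]
    values = mat.values.loc[genes]
    values = values[values.std(axis=1) > 0]  # processed-scale constant genes
    if values.shape[0] <= k:
        raise ValueError(
            f"only {values.shape[0]} genes pass filtering; need more than k={k}"
        )
    cor = correlation_matrix(values, spec.correlation)
    net = top_k_neighbors(cor, k, spec.correlation, workflow=vars(spec).copy())
    measures = network_quality_measures(
        net, annotations, alpha=alpha, min_term_size=min_term_size
    )
    row = {
        "dataset_id": dataset.name,
        "species": dataset.species,
        "n_samples": dataset.n_samples,
        "n_batches": dataset.n_batches,
        "normalization": spec.normalization,
        "correction": spec.correction,
        "correlation": spec.correlation,
        "workflow": spec.name,
    }
    row.update(measures.to_row())
    return row


def run_workflow_grid(
    datasets: list[CountDataset],
    specs: list[WorkflowSpec],
    annotations,
    k: int = 100,
    alpha: float = 0.05,
    min_term_size: int = 5,
) -> tuple[pd.DataFrame, QualityScoreTable]:
    """Evaluate every dataset x workflow cell and score the collection.

    *annotations* is either one domain -> sets mapping shared by all
    datasets, or a dict keyed by dataset name.  Per-network failures are
    logged and recorded as missing rows; the grid never aborts.
    Returns the measure table and the Quality-scored collection.
    """
    rows = []
    for dataset in datasets:
        annots = annotations.get(dataset.name, annotations) if isinstance(annotations, dict) and dataset.name in annotations else annotations
        for spec in specs:
            try:
                rows.append(run_workflow(dataset, spec, annots, k=k, alpha=alpha, min_term_size=min_term_size))
            except Exception as err:  # noqa: BLE001 - grid must survive cell failures
                logger.warning("workflow %s failed on dataset %s: %s", spec.name, dataset.name, err)
    table = pd.DataFrame(rows)
    scored = combine_quality(table)
    return table, scored


def split_train_validation(
    dataset_ids: list[str],
    species_of: dict[str, str] | pd.Series,
    fraction: float = 0.75,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Random train/validation split of dataset ids, stratified by species.

    Within each species, ``floor(fraction * n)`` ids go to training.
    Deterministic given *seed*; the two lists partition the input.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    species_of = pd.Series(dict(species_of)) if not isinstance(species_of, pd.Series) else species_of
    rng = np.random.default_rng(seed)
    train: list[str] = []
    validation: list[str] = []
    for sp in sorted(set(species_of.loc[dataset_ids])):
        ids = [d for d in dataset_ids if species_of[d] == sp]
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(fraction * len(ids)))
        train += [ids[i] for i in perm[:n_train]]
        validation += [ids[i] for i in perm[n_train:]]
    return sorted(train), sorted(validation)


@dataclass
class QualityModel:
    """Fitted OLS model of Quality on sample/batch counts and workflow."""

    summary: pd.DataFrame  # estimate, std_error, t_value, p_value per term
    n_obs: int
    df_resid: int
    r_squared: float
    baselines: dict[str, str] = field(default_factory=dict)

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["estimate"]

    def equivalent_sample_changes(self) -> pd.Series:
        """Percent sample-count change equivalent to each coefficient."""
        beta_n = self.coefficients["log10_samples"]
        terms = [t for t in self.summary.index if t not in ("intercept", "log10_samples")]
        return pd.Series(
            {t: equivalent_sample_change(self.coefficients[t], beta_n) for t in terms},
            name="equivalent_sample_change_pct",
        )


_BASELINES = {
    "species": "human",
    "normalization": "Quantile",
    "correction": "none",
    "correlation": "pearson",
}


def _design_matrix(table: pd.DataFrame, baselines: dict[str, str]) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    X["intercept"] = 1.0
    X["log10_samples"] = np.log10(table["n_samples"].astype(float))
    X["log10_batches"] = np.log10(table["n_batches"].astype(float))
    for factor in ("species", "normalization", "correction", "correlation"):
        levels = sorted(set(table[factor].astype(str)))
        base = baselines[factor]
        if len(levels) < 2:
            continue  # factor not varied in this collection
        if base not in levels:
            raise ValueError(f"baseline {base!r} absent from column {factor!r}")
        for lv in levels:
            if lv != base:
                X[f"{factor}_{lv}"] = (table[factor].astype(str) == lv).astype(float)
    return X


def fit_quality_model(
    table: pd.DataFrame, baselines: dict[str, str] | None = None
) -> QualityModel:
    """OLS of Quality on log10 counts and 0/1 workflow dummies.

    *table* needs columns quality, n_samples, n_batches, species,
    normalization, correction, correlation.  Baselines default to
    Quantile / no correction / Pearson / human.  Raises on a
    rank-deficient design, listing the aliased columns.
    """
    baselines = {**_BASELINES, **(baselines or {})}
    X = _design_matrix(table, baselines)
    y = table["quality"].astype(float)
    if len(table) <= X.shape[1]:
        raise ValueError("not enough observations to fit the model")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    summary = pd.DataFrame(
        {
            "estimate": fit.params,
            "std_error": fit.bse,
            "t_value": fit.tvalues,
            "p_value": fit.pvalues,
        },
        index=X.columns,
    )
    return QualityModel(
        summary=summary,
        n_obs=int(fit.nobs),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        baselines=baselines,
    )


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    aliased = []
    cols: list[str] = []
    arr = X.to_numpy()
    base_rank = 0
    kept: list[int] = []
    for j, name in enumerate(X.columns):
        trial = kept + [j]
        if np.linalg.matrix_rank(arr[:, trial]) > base_rank:
            kept = trial
            base_rank += 1
        else:
            aliased.append(name)
        cols.append(name)
    return aliased


def equivalent_sample_change(beta: float, beta_n: float) -> float:
    """Percent change in sample count with the same Quality effect as *beta*.

    Quality is linear in log10(sample count) with slope *beta_n*, so a
    coefficient beta corresponds to multiplying the sample count by
    ``10^(beta/beta_n)``; returned as a percent change (negative values
    are decreases).  Requires ``beta_n > 0``.
    """
    if beta_n <= 0:
        raise ValueError("beta_n must be positive")
    return 100.0 * (10.0 ** (beta / beta_n) - 1.0)


def cross_validate(
    table: pd.DataFrame,
    n_folds: int = 4,
    seed: int = 0,
    baselines: dict[str, str] | None = None,
) -> tuple[list[QualityModel], pd.DataFrame]:
    """Leave-one-fold-out refits over *dataset* folds (not network rows).

    Folds partition the dataset ids, stratified by species.  Returns the
    per-fold models and a coefficient matrix (terms x folds) for sign-
    consistency inspection.
    """
    ids = sorted(set(table["dataset_id"]))
    species_of = table.drop_duplicates("dataset_id").set_index("dataset_id")["species"]
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for sp in sorted(set(species_of)):
        sp_ids = [d for d in ids if species_of[d] == sp]
        perm = rng.permutation(len(sp_ids))
        for pos, i in enumerate(perm):
            folds[pos % n_folds].append(sp_ids[i])
    models = []
    coefs = {}
    for f, held_out in enumerate(folds):
        sub = table[~table["dataset_id"].isin(held_out)]
        model = fit_quality_model(sub, baselines=baselines)
        models.append(model)
        coefs[f"fold_{f + 1}"] = model.coefficients
    return models, pd.DataFrame(coefs)


def rank_workflows(scored_table: pd.DataFrame) -> pd.DataFrame:
    """Rank workflows by mean Quality across datasets.

    ``n_above_average`` counts, per workflow, the datasets on which its
    network's Quality exceeds that dataset's mean Quality over all
    workflows.  Ties in mean Quality are ordered by workflow name.
    """
    t = scored_table
    if t["workflow"].nunique() < 2:
        raise ValueError("need at least two workflows to rank")
    dataset_mean = t.groupby("dataset_id")["quality"].transform("mean")
    above = t.assign(above=(t["quality"] > dataset_mean))
    out = (
        above.groupby("workflow")
        .agg(mean_quality=("quality", "mean"), n_above_average=("above", "sum"), n_datasets=("dataset_id", "nunique"))
        .reset_index()
        .sort_values(["mean_quality", "workflow"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return out


def optimized_workflow_for(n_samples: int, threshold: int = 30) -> WorkflowSpec:
    """The recommended workflow: UQ + ComBat, Spearman below *threshold* samples."""
    correlation = "spearman" if n_samples < threshold else "pearson"
    return WorkflowSpec("UQ", "combat", correlation)


def compare_workflows_paired(
    measure_table: pd.DataFrame,
    default: WorkflowSpec,
    validation_ids: list[str],
    threshold: int = 30,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """One-sided paired t-tests of optimized vs default workflows.

    For every validation dataset the optimized workflow is UQ + ComBat
    with the correlation chosen by the dataset's sample count (Spearman
    below *threshold*).  For each of the eight measures the paired
    one-sided t statistic and p-value (alternative: optimized > default)
    and the count of improved datasets are reported.  Identical paired
    values (zero variance, zero mean difference) are reported as t = 0,
    p = 1, no improvement.
    """
    measures = list(measures) if measures is not None else list(MEASURE_COLUMNS)
    pairs = []
    for did in validation_ids:
        sub = measure_table[measure_table["dataset_id"] == did]
        if sub.empty:
            raise ValueError(f"no rows for validation dataset {did!r}")
        n_samples = int(sub["n_samples"].iloc[0])
        opt = optimized_workflow_for(n_samples, threshold)
        d_row = sub[sub["workflow"] == default.name]
        o_row = sub[sub["workflow"] == opt.name]
        if d_row.empty or o_row.empty:
            raise ValueError(f"dataset {did!r} lacks default or optimized workflow rows")
        pairs.append((d_row.iloc[0], o_row.iloc[0]))
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired observations")
    results = []
    for m in measures:
        d = np.array([o[m] - dflt[m] for dflt, o in pairs])
        if np.allclose(d, 0):
            t_stat, p = 0.0, 1.0
        elif d.std(ddof=1) == 0:
            # constant non-zero differences: degenerate paired t
            t_stat = np.inf if d.mean() > 0 else -np.inf
            p = 0.0 if d.mean() > 0 else 1.0
        else:
            t_stat, p = stats.ttest_rel(
                [o[m] for _, o in pairs], [dflt[m] for dflt, _ in pairs],
                alternative="greater",
            )
        results.append(
            {
                "measure": m,
                "t": float(t_stat),
                "p_value": float(p),
                "n_improved": int((d > 0).sum()),
                "n": len(d),
                "mean_difference": float(d.mean()),
            }
        )
    return pd.DataFrame(results)
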