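# coexqc

Quality-aware construction and benchmarking of RNA-seq gene
co-expression networks.

Public RNA-seq archives make it possible to estimate gene co-expression
for a cell type or tissue from hundreds or thousands of samples — but
those samples come from many studies, and the processing choices
(between-sample normalization, batch effect correction, correlation
measure) change the quality of the resulting networks substantially.
`coexqc` is for bioinformaticians who build such networks and want to
(a) run the standard processing workflows behind one interface, (b)
score the resulting networks with annotation-based quality measures, and
(c) quantify, in units everyone understands — *equivalent sample count* —
what each processing choice is worth.

## What it computes

For every gene *X* in a processed expression matrix, the network is the
set of the K = 100 genes most correlated with *X* (`set_X`). Network
quality is measured per annotation domain *d* ∈ {GO-MF, GO-BP, GO-CC,
TFBS}:

* *Enrichment_d* — fraction of genes whose `set_X` has ≥1 enriched term
  (one-sided hypergeometric test, BH-FDR ≤ 0.05 within domain);
* *Accuracy_d* — fraction of genes whose own annotations intersect the
  enriched terms of their `set_X`.

Across a collection of networks the eight standardized measures are
combined by PCA: **Quality** is the first principal component, oriented
so higher is better and min–max rescaled to [0, 1] over the collection.
Quality is then modeled as

```
Quality ~ log10(samples) + log10(batches) + species
          + normalization + correction + correlation      (OLS, 0/1 dummies)
```

and any coefficient β converts to an equivalent percent change in
sample count via `100·(10^(β/β_n) − 1)`, where β_n is the
log10-sample-count slope.

The package implements six normalizations (TMM, CPM, UQ, Med, a
simplified regularized log, Quantile), two batch correctors (linear
removal with protected biology covariates, and parametric
empirical-Bayes ComBat applied per confounding block), Pearson/Spearman
networks, the quality measures, the PCA score, and the workflow-grid
regression analysis — plus a synthetic data generator with known
co-expression modules, batch effects and matched GMT annotations for
validating the whole chain. See `docs/methods.md` for models and
defaults.

## Worked example

Simulate three multi-study datasets, run four workflows over them, and
rank the workflows by the Quality of the networks they produce:

```python
import pandas as pd
from coexqc import (
    SimulationConfig, generate_dataset, generate_annotations,
    WorkflowSpec, run_workflow_grid, rank_workflows,
    equivalent_sample_change, REFERENCE_COEFFICIENTS,
)

datasets, annotations = [], {}
for i, (n, b) in enumerate([(60, 3), (120, 6), (240, 8)]):
    cfg = SimulationConfig(n_genes=1000, n_samples=n, n_batches=b,
                           batch_loc_sd=1.0, seed=10 + i)
    ds, truth = generate_dataset(cfg, name=f"tissue_{i}")
    datasets.append(ds)
    annotations[ds.name] = generate_annotations(cfg, truth)

specs = [WorkflowSpec(n, c, "pearson")
         for n in ("UQ", "Quantile") for c in ("none", "combat")]
table, scored = run_workflow_grid(datasets, specs, annotations, k=100)
print(rank_workflows(scored.table).to_string(index=False))
print(f"PC1 explains {scored.pc1_variance_fraction:.1%} of measure variance")

beta_n = REFERENCE_COEFFICIENTS["log10_samples"]
pct = equivalent_sample_change(REFERENCE_COEFFICIENTS["correction_combat"], beta_n)
print(f"ComBat's coefficient is worth a {pct:.0f}% increase in sample count")
```

prints

```
               workflow  mean_quality  n_above_average  n_datasets
Quantile+combat+pearson      0.822836                3           3
      UQ+combat+pearson      0.816459                3           3
        UQ+none+pearson      0.188421                0           3
  Quantile+none+pearson      0.177823                0           3
PC1 explains 78.2% of measure variance
ComBat's coefficient is worth a 45% increase in sample count
```

With batch-effect sd 1.0 across 3–8 studies per dataset, both
batch-corrected workflows produce above-average networks on every
dataset and roughly quadruple the mean Quality of the uncorrected ones —
the eight underlying measures are consistent enough that one principal
component carries ~78% of their variance. The last line converts a
fitted ComBat coefficient from a published large-scale benchmark into
its equivalent sample-count increase: correcting batch effects bought as
much Quality as 45% more samples.

The same stages are scriptable from a shell:

```sh
coexqc simulate --config cfg.yaml --out sim/ --seed 7
coexqc normalize --method uq --in sim/counts.tsv --out norm.tsv
coexqc correct --method combat --in norm.tsv --meta sim/metadata.tsv --out corrected.tsv
coexqc network --method pearson --k 100 --in corrected.tsv --counts sim/counts.tsv --out net.tsv
coexqc analyze --quality-table quality.tsv --out report/
```

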