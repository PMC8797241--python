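"""Workflow enumeration, the Quality regression, and comparison utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexqc.analysis import (
    REFERENCE_COEFFICIENTS,
    WorkflowSpec,
    compare_workflows_paired,
    cross_validate,
    enumerate_workflows,
    equivalent_sample_change,
    fit_quality_model,
    rank_workflows,
    run_workflow_grid,
    split_train_validation,
)
from coexqc.enrichment import MEASURE_COLUMNS


def synthetic_quality_table(
    rng,
    n_datasets=24,
    species=("human", "mouse"),
    normalizations=("TMM", "CPM", "UQ", "Med", "Rlog", "Quantile"),
    corrections=("none", "linear", "combat"),
    correlations=("pearson", "spearman"),
    beta_n=0.3,
    beta_batch=-0.03,
    noise=0.02,
    effects=None,
):
    """A measure/quality table with a known generating model."""
    effects = effects or {}
    rows = []
    for d in range(n_datasets):
        sp = species[d % len(species)]
        n_samples = int(rng.integers(20, 500))
        n_batches = int(rng.integers(2, 12))
        for norm, corr, cmeth in itertools.product(normalizations, corrections, correlations):
            q = (
                0.1
                + beta_n * np.log10(n_samples)
                + beta_batch * np.log10(n_batches)
                + effects.get(("normalization", norm), 0.0)
                + effects.get(("correction", corr), 0.0)
                + effects.get(("correlation", cmeth), 0.0)
                + effects.get(("species", sp), 0.0)
                + rng.normal(0, noise)
            )
            rows.append(
                dict(
                    dataset_id=f"d{d:03d}",
                    species=sp,
                    n_samples=n_samples,
                    n_batches=n_batches,
                    normalization=norm,
                    correction=corr,
                    correlation=cmeth,
                    workflow=f"{norm}+{corr}+{cmeth}",
                    quality=q,
                )
            )
    return pd.DataFrame(rows)


class TestEnumeration:
    def test_full_design_has_fifty_unique_workflows(self):
        specs = enumerate_workflows()
        assert len(specs) == 50
        assert len(set(specs)) == 50
        # 6 normalizations x 4 corrections + combatseq-on-raw, x 2 correlations
        combatseq_raw = [s for s in specs if s.normalization == "none"]
        assert len(combatseq_raw) == 2
        assert all(s.correction == "combatseq" for s in combatseq_raw)

    def test_executable_subset_is_six_by_three_by_two(self):
        specs = enumerate_workflows(executable_only=True)
        assert len(specs) == 36
        assert all(s.correction != "combatseq" for s in specs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(normalization="none", correction="combat", correlation="pearson"),
            dict(normalization="UQ", correction="magic", correlation="pearson"),
            dict(normalization="UQ", correction="combat", correlation="kendall"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WorkflowSpec(**kwargs)


class TestSplit:
    def test_reference_split_counts(self):
        """68 human + 76 mouse datasets at 75%: 51 + 57 in training."""
        ids = [f"h{i}" for i in range(68)] + [f"m{i}" for i in range(76)]
        species = {d: ("human" if d.startswith("h") else "mouse") for d in ids}
        train, valid = split_train_validation(ids, species, fraction=0.75, seed=0)
        assert sum(d.startswith("h") for d in train) == 51
        assert sum(d.startswith("m") for d in train) == 57
        assert sorted(train + valid) == sorted(ids)

    def test_fraction_just_below_one_keeps_one_out(self):
        ids = list("abcd")
        train, valid = split_train_validation(ids, {i: "x" for i in ids}, fraction=0.999, seed=1)
        assert len(train) == 3 and len(valid) == 1

    def test_deterministic_given_seed(self):
        ids = [f"d{i}" for i in range(30)]
        species = {d: ("human" if i % 2 else "mouse") for i, d in enumerate(ids)}
        a = split_train_validation(ids, species, seed=9)
        b = split_train_validation(ids, species, seed=9)
        assert a == b

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_validation(["a"], {"a": "x"}, fraction=1.0)


class TestModelFit:
    def test_exact_linear_response_recovered(self, rng):
        effects = {
            ("normalization", "UQ"): 0.08,
            ("correction", "combat"): 0.05,
            ("correlation", "spearman"): -0.01,
            ("species", "mouse"): 0.04,
        }
        table = synthetic_quality_table(rng, noise=0.0, effects=effects)
        model = fit_quality_model(table)
        assert model.r_squared > 1 - 1e-12
        assert np.isclose(model.coefficients["log10_samples"], 0.3)
        assert np.isclose(model.coefficients["normalization_UQ"], 0.08)
        assert np.isclose(model.coefficients["correction_combat"], 0.05)
        assert np.isclose(model.coefficients["correlation_spearman"], -0.01)
        assert np.isclose(model.coefficients["species_mouse"], 0.04)

    def test_coefficients_match_pseudoinverse_oracle(self, rng):
        table = synthetic_quality_table(rng, n_datasets=10, noise=0.05)
        table = table.sample(200, random_state=7).reset_index(drop=True)
        model = fit_quality_model(table)
        from coexqc.analysis import _BASELINES, _design_matrix

        X = _design_matrix(table, _BASELINES).to_numpy()
        beta = np.linalg.pinv(X) @ table["quality"].to_numpy()
        assert np.abs(model.coefficients.to_numpy() - beta).max() < 1e-8

    def test_degrees_of_freedom_arithmetic(self, rng):
        table = synthetic_quality_table(rng, n_datasets=12)
        model = fit_quality_model(table)
        assert len(model.summary) == 12  # intercept + 2 counts + 9 dummies
        assert model.df_resid == model.n_obs - 12
        # t = estimate / SE and two-sided p from the t distribution
        t = model.summary["estimate"] / model.summary["std_error"]
        assert np.allclose(t, model.summary["t_value"])
        p = 2 * stats.t.sf(np.abs(t), model.df_resid)
        assert np.allclose(p, model.summary["p_value"])

    def test_row_order_invariance(self, rng):
        table = synthetic_quality_table(rng, n_datasets=8, noise=0.05)
        a = fit_quality_model(table)
        b = fit_quality_model(table.sample(frac=1.0, random_state=3).reset_index(drop=True))
        assert np.allclose(a.coefficients, b.coefficients)

    def test_rank_deficient_design_names_aliased_columns(self, rng):
        table = synthetic_quality_table(rng, n_datasets=8)
        # correlation choice fully determined by using ComBat: the two
        # dummies coincide and the design loses a rank
        table["correlation"] = np.where(table["correction"] == "combat", "spearman", "pearson")
        with pytest.raises(ValueError, match="aliased"):
            fit_quality_model(table)

    def test_missing_baseline_level_rejected(self, rng):
        table = synthetic_quality_table(rng, n_datasets=6, normalizations=("UQ", "Med"))
        with pytest.raises(ValueError, match="Quantile"):
            fit_quality_model(table)


class TestEquivalentSampleChange:
    def test_zero_and_one_decade(self):
        assert equivalent_sample_change(0.0, 0.3) == 0.0
        assert np.isclose(equivalent_sample_change(0.3, 0.3), 900.0)

    def test_reference_conversions_reproduce_published_percentages(self):
        beta_n = REFERENCE_COEFFICIENTS["log10_samples"]
        assert round(equivalent_sample_change(REFERENCE_COEFFICIENTS["normalization_UQ"], beta_n)) == 86
        assert round(equivalent_sample_change(REFERENCE_COEFFICIENTS["normalization_Med"], beta_n)) == 66
        assert round(equivalent_sample_change(REFERENCE_COEFFICIENTS["correction_combat"], beta_n)) == 45
        assert round(equivalent_sample_change(REFERENCE_COEFFICIENTS["correction_linear"], beta_n)) == 39
        assert round(equivalent_sample_change(REFERENCE_COEFFICIENTS["correlation_spearman"], beta_n), 1) == -8.2

    def test_inverse_identity_and_monotonicity(self, rng):
        beta_n = 0.29
        for beta in rng.uniform(-0.2, 0.2, size=20):
            pct = equivalent_sample_change(beta, beta_n)
            assert np.isclose(beta, beta_n * np.log10(1 + pct / 100))
        grid = np.linspace(-0.2, 0.2, 41)
        vals = [equivalent_sample_change(b, beta_n) for b in grid]
        assert (np.diff(vals) > 0).all()

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            equivalent_sample_change(0.1, 0.0)


class TestCrossValidation:
    def test_folds_partition_datasets(self, rng):
        table = synthetic_quality_table(rng, n_datasets=16, noise=0.05)
        models, coefs = cross_validate(table, n_folds=4, seed=2)
        assert len(models) == 4 and coefs.shape[1] == 4
        total = sum(m.n_obs for m in models)
        assert total == 3 * len(table)  # each row held out exactly once

    def test_pure_sample_count_model_stable_across_folds(self, rng):
        table = synthetic_quality_table(rng, n_datasets=20, noise=0.0)
        _, coefs = cross_validate(table, n_folds=4, seed=0)
        spread = coefs.loc["log10_samples"].max() - coefs.loc["log10_samples"].min()
        assert spread < 1e-10

    def test_injected_negative_batch_coefficient_consistent(self, rng):
        table = synthetic_quality_table(rng, n_datasets=24, beta_batch=-0.05, noise=0.02)
        _, coefs = cross_validate(table, n_folds=4, seed=5)
        assert (coefs.loc["log10_batches"] < 0).all()
        assert (coefs.loc["log10_samples"] > 0).all()


class TestRanking:
    def test_dominating_workflow_counts_every_dataset(self, rng):
        effects = {("normalization", "UQ"): 0.5}
        table = synthetic_quality_table(
            rng, n_datasets=6, normalizations=("UQ", "CPM"), corrections=("none",),
            noise=0.001, effects=effects,
        )
        ranking = rank_workflows(table)
        top = ranking.iloc[0]
        assert top["workflow"].startswith("UQ")
        uq_rows = ranking[ranking["workflow"].str.startswith("UQ")]
        assert (uq_rows["n_above_average"] == 6).all()

    def test_toy_table_matches_brute_force(self):
        rows = []
        qualities = {
            ("w1", "d1"): 0.9, ("w1", "d2"): 0.2, ("w1", "d3"): 0.65,
            ("w2", "d1"): 0.5, ("w2", "d2"): 0.8, ("w2", "d3"): 0.4,
            ("w3", "d1"): 0.1, ("w3", "d2"): 0.3, ("w3", "d3"): 0.5,
        }
        for (w, d), q in qualities.items():
            rows.append(dict(workflow=w, dataset_id=d, quality=q))
        ranking = rank_workflows(pd.DataFrame(rows))
        means = {w: np.mean([qualities[(w, d)] for d in ("d1", "d2", "d3")]) for w in ("w1", "w2", "w3")}
        expect_order = sorted(means, key=lambda w: -means[w])
        assert list(ranking["workflow"]) == expect_order
        d_means = {d: np.mean([qualities[(w, d)] for w in ("w1", "w2", "w3")]) for d in ("d1", "d2", "d3")}
        for _, r in ranking.iterrows():
            expect = sum(qualities[(r["workflow"], d)] > d_means[d] for d in d_means)
            assert r["n_above_average"] == expect

    def test_equal_means_ordered_by_name(self):
        rows = [
            dict(workflow="beta", dataset_id="d1", quality=0.4),
            dict(workflow="beta", dataset_id="d2", quality=0.6),
            dict(workflow="alpha", dataset_id="d1", quality=0.6),
            dict(workflow="alpha", dataset_id="d2", quality=0.4),
        ]
        ranking = rank_workflows(pd.DataFrame(rows))
        assert list(ranking["workflow"]) == ["alpha", "beta"]


class TestPairedComparison:
    @staticmethod
    def measure_table(diffs_by_dataset, n_samples=50):
        """Default and optimized rows per dataset with a fixed measure shift."""
        rows = []
        for did, diff in diffs_by_dataset.items():
            base = dict(dataset_id=did, n_samples=n_samples, n_batches=3)
            d = dict(base, workflow="Rlog+none+pearson")
            o = dict(base, workflow="UQ+combat+pearson" if n_samples >= 30 else "UQ+combat+spearman")
            for m in MEASURE_COLUMNS:
                d[m] = 0.4
                o[m] = 0.4 + diff
            rows += [d, o]
        return pd.DataFrame(rows)

    def test_identical_workflows_report_no_improvement(self):
        table = self.measure_table({f"d{i}": 0.0 for i in range(5)})
        res = compare_workflows_paired(
            table, WorkflowSpec("Rlog", "none", "pearson"), [f"d{i}" for i in range(5)]
        )
        assert (res["t"] == 0).all() and (res["p_value"] == 1).all()
        assert (res["n_improved"] == 0).all()

    def test_constant_improvement_matches_degenerate_t(self):
        table = self.measure_table({f"d{i}": 0.1 for i in range(6)})
        res = compare_workflows_paired(
            table, WorkflowSpec("Rlog", "none", "pearson"), [f"d{i}" for i in range(6)]
        )
        assert (res["n_improved"] == 6).all()
        assert (res["p_value"] == 0).all()

    def test_one_sided_p_matches_exact_t_distribution(self, rng):
        diffs = {f"d{i}": float(x) for i, x in enumerate([0.1, -0.1, 0.05, -0.05])}
        table = self.measure_table(diffs)
        res = compare_workflows_paired(
            table, WorkflowSpec("Rlog", "none", "pearson"), list(diffs)
        )
        d = np.array(list(diffs.values()))
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = stats.t.sf(t, len(d) - 1)
        assert np.allclose(res["t"], t)
        assert np.allclose(res["p_value"], p)

    def test_correlation_choice_follows_sample_threshold(self):
        small = self.measure_table({"d1": 0.1, "d2": 0.1, "d3": 0.1}, n_samples=20)
        res = compare_workflows_paired(
            small, WorkflowSpec("Rlog", "none", "pearson"), ["d1", "d2", "d3"]
        )
        assert (res["n_improved"] == 3).all()  # matched the spearman rows

    def test_too_few_pairs_rejected(self):
        table = self.measure_table({"d1": 0.1, "d2": 0.1})
        with pytest.raises(ValueError, match="3 paired"):
            compare_workflows_paired(table, WorkflowSpec("Rlog", "none", "pearson"), ["d1", "d2"])


def test_grid_produces_one_row_per_dataset_workflow_cell(small_sim):
    cfg, ds, truth, annots = small_sim
    from coexqc.simulate import generate_annotations, generate_dataset

    cfg2 = cfg.updated(seed=cfg.seed + 1)
    ds2, truth2 = generate_dataset(cfg2, name="sim_b")
    annots2 = generate_annotations(cfg2, truth2)
    specs = [
        WorkflowSpec("UQ", "none", "pearson"),
        WorkflowSpec("UQ", "combat", "pearson"),
        WorkflowSpec("CPM", "none", "spearman"),
        WorkflowSpec("Quantile", "linear", "spearman"),
    ]
    table, scored = run_workflow_grid(
        [ds, ds2], specs, {ds.name: annots, "sim_b": annots2}, k=50
    )
    assert len(table) == 8
    assert set(table["workflow"]) == {s.name for s in specs}
    assert scored.table["quality"].between(0, 1).all()
    assert np.isclose(scored.table["quality"].min(), 0.0)
    assert np.isclose(scored.table["quality"].max(), 1.0)


def test_grid_records_failures_as_missing_rows(small_sim, caplog):
    cfg, ds, _, annots = small_sim
    from coexqc.simulate import generate_annotations, generate_dataset

    others = []
    annot_map = {ds.name: annots}
    for i in (5, 6):
        c = cfg.updated(seed=cfg.seed + i)
        d, t = generate_dataset(c, name=f"sim_extra{i}")
        others.append(d)
        annot_map[d.name] = generate_annotations(c, t)
    specs = [
        WorkflowSpec("UQ", "none", "pearson"),
        WorkflowSpec("CPM", "none", "spearman"),
        WorkflowSpec("none", "combatseq", "pearson"),  # not executable
    ]
    import logging

    with caplog.at_level(logging.WARNING, logger="coexqc.analysis"):
        table, scored = run_workflow_grid([ds] + others, specs, annot_map, k=50)
    assert len(table) == 6  # combatseq rows missing, grid not aborted
    assert "combatseq" in caplog.text
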