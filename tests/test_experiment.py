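"""Grid enumeration, meta-regression, follow-ups and checkpointing."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from burdenml import (
    GridCell,
    GridSpec,
    build_design,
    cells_frame,
    enumerate_cells,
    meta_regress,
    run_followup_no_expression,
    run_followup_sensitive,
    run_grid,
)
from burdenml.classify import METHODS, ClassifierSpec

FAST_CLASSIFIER = ClassifierSpec(tuning_grid={"C": (1.0,), "gamma": (0.1,)})


def tiny_spec(**kwargs) -> GridSpec:
    base = dict(
        gene_lists=(("causal", 1), ("none", 0)),
        noise_levels=(0.0, 0.01),
        selection_replicate_ids=tuple(f"SIMPHEN.{i}" for i in range(1, 21)),
        classification_replicate_ids=("SIMPHEN.24",),
        collapse_depths=(2, 4),
        classifier=FAST_CLASSIFIER,
        seed=3,
    )
    base.update(kwargs)
    return GridSpec(**base)


# --- enumeration --------------------------------------------------------------

def test_default_grid_has_315_cells():
    spec = GridSpec(classification_replicate_ids=("a", "b", "c"),
                    selection_replicate_ids=tuple(f"r{i}" for i in range(150)))
    assert len(enumerate_cells(spec)) == 7 * 3 * 3 * 5


def test_singleton_grid_has_one_cell():
    spec = tiny_spec(gene_lists=(("causal", 1),), noise_levels=(0.0,),
                     collapse_depths=(5,))
    assert len(enumerate_cells(spec)) == 1


def test_sensitive_followup_menu_has_15_cells():
    spec = tiny_spec(
        gene_lists=(("causal", 1), ("causal", 5), ("causal", 10)),
        noise_levels=(0.0,),
        collapse_depths=(5, 25, 50, 100, 150),
        selection_replicate_ids=tuple(f"r{i}" for i in range(150)),
        phenotype_mode="sensitive",
    )
    assert len(enumerate_cells(spec)) == 15


def test_cardinality_is_product_of_menu_sizes():
    rng = np.random.default_rng(0)
    for _ in range(10):
        lists = tuple(("causal", int(s)) for s in rng.integers(1, 9, rng.integers(1, 5)))
        ks = tuple(float(k) for k in rng.uniform(0, 1, rng.integers(1, 4)))
        reps = tuple(f"r{i}" for i in range(rng.integers(1, 4)))
        ms = tuple(int(m) for m in rng.integers(1, 10, rng.integers(1, 4)))
        spec = tiny_spec(gene_lists=lists, noise_levels=ks,
                         classification_replicate_ids=reps, collapse_depths=ms,
                         selection_replicate_ids=tuple(f"s{i}" for i in range(10)))
        assert len(enumerate_cells(spec)) == len(lists) * len(ks) * len(reps) * len(ms)


def test_overlapping_replicate_sets_rejected():
    with pytest.raises(ValueError, match="overlap"):
        tiny_spec(classification_replicate_ids=("SIMPHEN.1",)).validate()


def test_collapse_depth_exceeding_selection_replicates_rejected():
    with pytest.raises(ValueError, match="depth"):
        tiny_spec(collapse_depths=(21,)).validate()


# --- meta-regression ----------------------------------------------------------

def planted_cells(coefs: dict[str, float], sigma: float = 0.0, seed: int = 0):
    """Grid cells whose AUC is an exact linear function of the design factors."""
    rng = np.random.default_rng(seed)
    cells = []
    for kind, size in [("causal", 1), ("causal", 10), ("noncausal", 5),
                       ("noncausal", 50), ("none", 0)]:
        for k in (0.0, 0.01, 0.1):
            for m in (5, 50, 150):
                cell = GridCell(kind, size, k, "rep", m)
                nc = size if kind == "causal" else 0
                nn = size if kind == "noncausal" else 0
                auc = (coefs.get("intercept", 0.8) + coefs.get("n_causal", 0.0) * nc
                       + coefs.get("n_noncausal", 0.0) * nn + coefs.get("k", 0.0) * k
                       + coefs.get("m", 0.0) * m)
                cell.auc_by_method = {mth: auc + sigma * rng.normal() for mth in METHODS}
                cell.best_methods = list(METHODS)
                cells.append(cell)
    return cells


def test_planted_noncausal_coefficient_recovered_within_3_se():
    cells = planted_cells({"n_noncausal": -0.001}, sigma=1e-4, seed=1)
    fit = meta_regress(cells)
    for mth in METHODS:
        row = fit.coefficients[mth].loc["n_noncausal_genes"]
        assert abs(row["estimate"] - (-0.001)) < 3 * row["se"]


def test_noise_free_planted_table_has_unit_r_squared():
    cells = planted_cells({"n_causal": 2e-3, "n_noncausal": -1e-3, "k": -0.05,
                           "m": -1e-4})
    fit = meta_regress(cells)
    for mth in METHODS:
        assert fit.r_squared[mth] == pytest.approx(1.0, abs=1e-9)


def test_meta_regression_matches_normal_equations_oracle():
    cells = planted_cells({"n_noncausal": -0.002, "k": -0.1}, sigma=5e-3, seed=2)[::4][:10]
    fit = meta_regress(cells)
    table = cells_frame(cells)
    sub = table[table["method"] == "logistic"]
    X = np.column_stack([np.ones(len(sub)),
                         sub[["n_causal_genes", "n_noncausal_genes", "k", "m"]]])
    beta = np.linalg.solve(X.T @ X, X.T @ sub["auc"].to_numpy())
    got = fit.coefficients["logistic"]["estimate"].to_numpy()
    assert np.allclose(got, beta, atol=1e-10)


def test_constant_predictor_named_in_error():
    cells = [c for c in planted_cells({"n_noncausal": -1e-3}) if c.k == 0.0]
    with pytest.raises(ValueError, match="'k'"):
        meta_regress(cells)


def test_significance_stars_follow_thresholds():
    cells = planted_cells({"n_noncausal": -0.002}, sigma=1e-5, seed=3)
    fit = meta_regress(cells)
    stars = fit.stars("logistic")
    assert stars["n_noncausal_genes"] == "***"


# --- grid execution -----------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_grid_cells(small_cohort):
    return run_grid(small_cohort, tiny_spec())


def test_grid_runs_every_cell(tiny_grid_cells):
    assert len(tiny_grid_cells) == 2 * 2 * 1 * 2
    assert all(c.failed is None for c in tiny_grid_cells)
    for c in tiny_grid_cells:
        assert set(c.auc_by_method) == set(METHODS)
        assert all(0.0 <= a <= 1.0 for a in c.auc_by_method.values())


def test_best_method_attains_maximum_and_ties_listed(tiny_grid_cells):
    for c in tiny_grid_cells:
        best = max(c.auc_by_method.values())
        expect = [mth for mth, a in c.auc_by_method.items() if a == best]
        assert c.best_methods == expect


def test_win_counts_sum_to_cells_plus_tie_multiplicities(tiny_grid_cells):
    total = sum(len(c.best_methods) for c in tiny_grid_cells)
    frame = cells_frame(tiny_grid_cells)
    assert int(frame["best"].sum()) == total
    assert total >= len(tiny_grid_cells)


def test_grid_rerun_is_bit_identical(small_cohort, tiny_grid_cells):
    again = run_grid(small_cohort, tiny_spec())
    for a, b in zip(tiny_grid_cells, again):
        assert a.cell_id == b.cell_id
        assert a.auc_by_method == b.auc_by_method  # exact float equality
        assert a.gene_ids == b.gene_ids


def test_checkpoint_resume_reuses_and_completes(small_cohort, tiny_grid_cells, tmp_path):
    import json

    path = tmp_path / "cells.jsonl"
    # pre-populate with the first three finished cells, then resume
    with path.open("w") as fh:
        for c in tiny_grid_cells[:3]:
            fh.write(json.dumps(c.to_dict()) + "\n")
    resumed = run_grid(small_cohort, tiny_spec(), checkpoint_path=path)
    assert [c.cell_id for c in resumed] == [c.cell_id for c in tiny_grid_cells]
    for a, b in zip(resumed, tiny_grid_cells):
        assert a.auc_by_method == b.auc_by_method
    # the file now holds every cell exactly once
    lines = [json.loads(l) for l in path.read_text().splitlines()]
    assert len(lines) == len(tiny_grid_cells)


def test_impossible_list_size_marks_cell_failed(small_cohort):
    cells = run_grid(small_cohort, tiny_spec(gene_lists=(("causal", 99),)))
    assert all(c.failed is not None for c in cells)
    assert any("99" in c.failed for c in cells)


# --- follow-ups ---------------------------------------------------------------

def test_followup_no_expression_table_layout(small_cohort):
    table = run_followup_no_expression(
        small_cohort,
        tiny_spec(),
        causal_sizes=(1, 2),
        m=2,
    )
    assert list(table.index) == [1, 2]
    assert table.shape == (2, 6)  # 3 methods x with/without
    assert set(table.columns.get_level_values("method")) == set(METHODS)
    assert set(table.columns.get_level_values("expression")) == {
        "with_expression", "without_expression"
    }
    assert ((table >= 0) & (table <= 1)).all().all()


def test_no_expression_design_has_one_column_per_gene(small_cohort):
    genes = small_cohort.gene_ids[:4]
    d = build_design(small_cohort, genes, include_expression=False)
    assert len(d.gene_columns()) + len(d.dropped_columns) == len(genes)


def test_followup_sensitive_improvement_is_zero_at_m_one(small_cohort):
    table = run_followup_sensitive(
        small_cohort,
        tiny_spec(collapse_depths=(1,)),
        causal_sizes=(1, 2),
        n_bootstrap=100,
    )
    # specific and sensitive collapse coincide at m = 1, so the whole
    # pipeline produces identical AUCs and the improvement is exactly zero
    assert (table["mean_improvement"] == 0.0).all()
    assert (table["ci_low"] == 0.0).all()
    assert (table["ci_high"] == 0.0).all()
    assert (table["n_settings"] == 2).all()


def test_sensitive_mode_never_has_fewer_cases(small_cohort):
    from burdenml import collapse

    reps = small_cohort.phenotype_replicates
    for m in (1, 3, 5, 10, 20):
        y = collapse(reps, "specific", m=m).case_count
        z = collapse(reps, "sensitive", m=m).case_count
        assert z >= y
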