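"""Factorial evaluation grid, AUC meta-regression and follow-up analyses.

The default grid crosses 7 gene lists (top 1/5/10 causal, top 5/15/50
non-causal, and the covariates-only baseline) with 3 expression-noise levels
k, 3 held-out classification replicates, and 5 collapse depths m — 315 cells.
Per cell the selection phenotype is collapsed at m, Uniform(-k, k) noise is
added to the selection expression, genes are re-ranked, the three
classifiers are trained on the selection data, and each is scored by AUC
against the raw binary status of the held-out classification replicate.

``meta_regress`` then summarises each method's 315 AUCs by an
ordinary-least-squares regression on the design factors (numbers of causal
and non-causal genes, k, m).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .classify import METHODS, ClassifierSpec, compute_auc, fit_classifier, predict_scores
from .cohort import Cohort
from .features import (
    DEFAULT_MAF_THRESHOLD,
    build_design,
    in_sample_maf,
    inject_expression_noise,
)
from .phenotypes import collapse
from .selection import GeneTestResult, rank_genes, select_top_genes

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "GridCell",
    "MetaRegressionFit",
    "enumerate_cells",
    "run_grid",
    "meta_regress",
    "run_followup_no_expression",
    "run_followup_sensitive",
    "cells_frame",
]

DEFAULT_GENE_LISTS: tuple[tuple[str, int], ...] = (
    ("causal", 1),
    ("causal", 5),
    ("causal", 10),
    ("noncausal", 5),
    ("noncausal", 15),
    ("noncausal", 50),
    ("none", 0),
)

META_PREDICTORS = ("n_causal_genes", "n_noncausal_genes", "k", "m")


def derive_seed(base: int, *parts) -> int:
    """Deterministic sub-seed below 2**31 from a base seed and labels."""
    tag = zlib.crc32("|".join(str(p) for p in parts).encode())
    return int(np.random.SeedSequence([int(base), tag]).generate_state(1)[0] % (2**31))


@dataclass
class GridSpec:
    """Menus defining the factorial evaluation grid."""

    gene_lists: tuple[tuple[str, int], ...] = DEFAULT_GENE_LISTS
    noise_levels: tuple[float, ...] = (0.0, 0.01, 0.1)
    selection_replicate_ids: tuple[str, ...] | None = None  # default: SIMPHEN.1..150
    classification_replicate_ids: tuple[str, ...] | None = None  # default: last 3
    collapse_depths: tuple[int, ...] = (5, 25, 50, 100, 150)
    phenotype_mode: str = "specific"
    include_expression: bool = True
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    seed: int = 0

    def resolve(self, cohort: Cohort) -> "GridSpec":
        """Fill replicate-set defaults from the cohort's replicate table."""
        cols = list(cohort.phenotype_replicates.columns)
        sel = self.selection_replicate_ids
        cls = self.classification_replicate_ids
        if cls is None:
            # mirror the convention of holding out replicates 197-199 when
            # the cohort has that many; otherwise the last three
            cls = tuple(cols[196:199]) if len(cols) >= 199 else tuple(cols[-3:])
        if sel is None:
            sel = tuple(c for c in cols[: min(150, len(cols))] if c not in set(cls))
        spec = replace(self, selection_replicate_ids=tuple(sel), classification_replicate_ids=tuple(cls))
        spec.validate()
        return spec

    def validate(self) -> None:
        if not self.gene_lists or not self.noise_levels or not self.collapse_depths:
            raise ValueError("grid menus must be non-empty")
        sel = set(self.selection_replicate_ids or ())
        cls = set(self.classification_replicate_ids or ())
        if sel & cls:
            raise ValueError(f"selection and classification replicates overlap: {sorted(sel & cls)}")
        if self.selection_replicate_ids is not None:
            if max(self.collapse_depths) > len(self.selection_replicate_ids):
                raise ValueError("collapse depth m exceeds the selection replicate count")


@dataclass
class GridCell:
    """One grid combination with the per-method AUCs."""

    gene_list_kind: str
    gene_list_size: int
    k: float
    classification_replicate_id: str
    m: int
    mode: str = "specific"
    include_expression: bool = True
    auc_by_method: dict[str, float] = field(default_factory=dict)
    best_methods: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    hyperparameters: dict[str, dict[str, float]] = field(default_factory=dict)
    failed: str | None = None

    @property
    def n_causal(self) -> int:
        return self.gene_list_size if self.gene_list_kind == "causal" else 0

    @property
    def n_noncausal(self) -> int:
        return self.gene_list_size if self.gene_list_kind == "noncausal" else 0

    @property
    def cell_id(self) -> str:
        return (
            f"{self.gene_list_kind}{self.gene_list_size}|k={self.k}|"
            f"rep={self.classification_replicate_id}|m={self.m}|{self.mode}|"
            f"expr={int(self.include_expression)}"
        )

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "gene_list_kind": self.gene_list_kind,
            "gene_list_size": self.gene_list_size,
            "k": self.k,
            "classification_replicate_id": self.classification_replicate_id,
            "m": self.m,
            "mode": self.mode,
            "include_expression": self.include_expression,
            "auc_by_method": self.auc_by_method,
            "best_methods": self.best_methods,
            "gene_ids": self.gene_ids,
            "hyperparameters": self.hyperparameters,
            "failed": self.failed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridCell":
        d = dict(d)
        d.pop("cell_id", None)
        return cls(**d)


def enumerate_cells(spec: GridSpec) -> list[GridCell]:
    """The full cross-product of the grid menus, in deterministic order."""
    cells = []
    for kind, size in spec.gene_lists:
        for k in spec.noise_levels:
            for rep in spec.classification_replicate_ids or ("<unresolved>",):
                for m in spec.collapse_depths:
                    cells.append(
                        GridCell(
                            gene_list_kind=kind,
                            gene_list_size=size,
                            k=k,
                            classification_replicate_id=rep,
                            m=m,
                            mode=spec.phenotype_mode,
                            include_expression=spec.include_expression,
                        )
                    )
    return cells


class _GridEngine:
    """Caches shared across grid cells.

    Gene ranking depends only on (m, k); trained classifiers depend on
    (m, k, gene list); both are reused across the classification replicates,
    which only change the truth labels the predictions are scored against.
    """

    def __init__(self, cohort: Cohort, spec: GridSpec):
        self.cohort = cohort
        self.spec = spec
        self.maf = in_sample_maf(cohort.genotypes)
        self.selection = cohort.phenotype_replicates[list(spec.selection_replicate_ids)]
        self._rank_cache: dict = {}
        self._model_cache: dict = {}
        self._test_design_cache: dict = {}

    def ranked(self, m: int, k: float) -> tuple[list[GeneTestResult], pd.DataFrame, pd.Series]:
        key = (m, k, self.spec.phenotype_mode, self.spec.include_expression)
        if key not in self._rank_cache:
            phen = collapse(self.selection, mode=self.spec.phenotype_mode, m=m)
            noisy = inject_expression_noise(
                self.cohort.expression, k, derive_seed(self.spec.seed, "noise", m, k)
            )
            results = rank_genes(
                self.cohort,
                phen,
                include_expression=self.spec.include_expression,
                maf_threshold=self.spec.maf_threshold,
                expression=noisy,
            )
            self._rank_cache[key] = (results, noisy, phen.status)
        return self._rank_cache[key]

    def models(self, kind: str, size: int, m: int, k: float):
        # the no-gene baseline has no expression columns, so its training
        # problem is identical across noise levels — share the fit
        key_k = None if kind == "none" else k
        key = (kind, size, m, key_k, self.spec.phenotype_mode, self.spec.include_expression)
        if key not in self._model_cache:
            results, noisy, status = self.ranked(m, k)
            genes = [] if kind == "none" else select_top_genes(results, kind, size).gene_ids
            train = build_design(
                self.cohort,
                genes,
                include_expression=self.spec.include_expression,
                maf_threshold=self.spec.maf_threshold,
                expression=noisy,
                maf=self.maf,
            )
            fitted = {}
            for method in METHODS:
                cspec = replace(
                    self.spec.classifier,
                    method=method,
                    seed=derive_seed(self.spec.seed, "fit", kind, size, m, key_k, method),
                )
                fitted[method] = fit_classifier(train, status, cspec)
            self._model_cache[key] = (genes, fitted)
        return self._model_cache[key]

    def test_design(self, genes: tuple[str, ...]):
        key = (genes, self.spec.include_expression)
        if key not in self._test_design_cache:
            # classification-stage design uses the unperturbed expression
            self._test_design_cache[key] = build_design(
                self.cohort,
                list(genes),
                include_expression=self.spec.include_expression,
                maf_threshold=self.spec.maf_threshold,
                maf=self.maf,
            )
        return self._test_design_cache[key]

    def run_cell(self, cell: GridCell) -> GridCell:
        try:
            genes, fitted = self.models(cell.gene_list_kind, cell.gene_list_size, cell.m, cell.k)
            truth = self.cohort.phenotype_replicates[cell.classification_replicate_id]
            test = self.test_design(tuple(genes))
            aucs, hypers = {}, {}
            for method, model in fitted.items():
                # train/test designs can differ in which constant gene columns
                # were dropped; align the test frame to the training columns
                if test.columns != model.columns:
                    missing = set(model.columns) - set(test.frame.columns)
                    if missing:
                        raise ValueError(f"training columns absent at classification: {sorted(missing)}")
                    test_aligned = replace(test, frame=test.frame[model.columns])
                else:
                    test_aligned = test
                scores = predict_scores(model, test_aligned)
                aucs[method] = compute_auc(scores, truth)
                hypers[method] = model.hyperparameters
            best = max(aucs.values())
            cell.auc_by_method = aucs
            cell.best_methods = [mth for mth, a in aucs.items() if a == best]
            cell.gene_ids = list(genes)
            cell.hyperparameters = hypers
        except Exception as exc:
            logger.warning("cell %s failed: %s", cell.cell_id, exc)
            cell.failed = str(exc)
        return cell


def run_grid(
    cohort: Cohort,
    spec: GridSpec,
    checkpoint_path: str | Path | None = None,
    progress: bool = False,
) -> list[GridCell]:
    """Execute every cell of the grid; failures mark cells, never abort.

    With ``checkpoint_path``, finished cells are appended to a JSON-lines
    file as they complete and already-present cells are skipped on re-run,
    making long grids resumable.
    """
    spec = spec.resolve(cohort)
    engine = _GridEngine(cohort, spec)
    cells = enumerate_cells(spec)
    done: dict[str, GridCell] = {}
    handle = None
    if checkpoint_path is not None:
        path = Path(checkpoint_path)
        if path.exists():
            for line in path.read_text().splitlines():
                if line.strip():
                    c = GridCell.from_dict(json.loads(line))
                    done[c.cell_id] = c
        handle = path.open("a")
    out = []
    try:
        for i, cell in enumerate(cells):
            if cell.cell_id in done:
                out.append(done[cell.cell_id])
                continue
            cell = engine.run_cell(cell)
            out.append(cell)
            if handle is not None:
                handle.write(json.dumps(cell.to_dict()) + "\n")
                handle.flush()
            if progress and (i + 1) % 10 == 0:
                logger.info("grid: %d/%d cells done", i + 1, len(cells))
    finally:
        if handle is not None:
            handle.close()
    return out


def cells_frame(cells: list[GridCell]) -> pd.DataFrame:
    """Long-format table: one row per (cell, method) with its AUC."""
    rows = []
    for c in cells:
        for method, auc in c.auc_by_method.items():
            rows.append(
                {
                    "gene_list_kind": c.gene_list_kind,
                    "gene_list_size": c.gene_list_size,
                    "n_causal_genes": c.n_causal,
                    "n_noncausal_genes": c.n_noncausal,
                    "k": c.k,
                    "classification_replicate_id": c.classification_replicate_id,
                    "m": c.m,
                    "mode": c.mode,
                    "include_expression": c.include_expression,
                    "method": method,
                    "auc": auc,
                    "best": method in c.best_methods,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MetaRegressionFit:
    """Per-method OLS of AUC on the grid factors."""

    coefficients: dict[str, pd.DataFrame]  # method -> table(estimate, se, p_value)
    r_squared: dict[str, float]

    def stars(self, method: str) -> pd.Series:
        p = self.coefficients[method]["p_value"]
        return p.map(lambda v: "***" if v < 1e-3 else "**" if v < 1e-2 else "*" if v < 0.05 else "")


def meta_regress(cells: list[GridCell]) -> MetaRegressionFit:
    """OLS of per-cell AUC on n_causal, n_noncausal, k and m, per method.

    Baseline (no-gene) cells enter with both gene counts at zero.  Every
    predictor must vary across cells; a constant one raises with its name.
    """
    table = cells_frame([c for c in cells if c.failed is None])
    if table.empty:
        raise ValueError("no successful cells to regress on")
    coefficients, r2 = {}, {}
    for method in sorted(table["method"].unique()):
        sub = table[table["method"] == method]
        if len(sub) < 5:
            raise ValueError(f"need >= 5 cells per method, got {len(sub)} for {method}")
        X = sub[list(META_PREDICTORS)].astype(float)
        for col in META_PREDICTORS:
            if X[col].nunique() <= 1:
                raise ValueError(f"predictor {col!r} is constant across cells")
        fit = sm.OLS(sub["auc"].to_numpy(), sm.add_constant(X.to_numpy())).fit()
        names = ["intercept", *META_PREDICTORS]
        coefficients[method] = pd.DataFrame(
            {"estimate": fit.params, "se": fit.bse, "p_value": fit.pvalues}, index=names
        )
        r2[method] = float(fit.rsquared)
    return MetaRegressionFit(coefficients=coefficients, r_squared=r2)


def run_followup_no_expression(
    cohort: Cohort,
    spec: GridSpec | None = None,
    causal_sizes: tuple[int, ...] = (1, 5, 10),
    m: int = 5,
) -> pd.DataFrame:
    """AUC with vs without the expression terms, for the top-causal lists.

    Runs paired cells (k = 0, one classification replicate, one collapse
    depth) with the expression main effect and interaction included or with
    the burden indicator alone, and tabulates the AUCs side by side: one row
    per causal-list size, columns (method, with/without expression).
    """
    spec = (spec or GridSpec()).resolve(cohort)
    rep = spec.classification_replicate_ids[0]
    rows: dict[int, dict] = {size: {} for size in causal_sizes}
    for include in (True, False):
        sub = replace(
            spec,
            gene_lists=tuple(("causal", s) for s in causal_sizes),
            noise_levels=(0.0,),
            classification_replicate_ids=(rep,),
            collapse_depths=(m,),
            include_expression=include,
        )
        for cell in run_grid(cohort, sub):
            label = "with_expression" if include else "without_expression"
            for method, auc in cell.auc_by_method.items():
                rows[cell.gene_list_size][(method, label)] = auc
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "n_causal_genes"
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["method", "expression"])
    return out.sort_index(axis=1)


def run_followup_sensitive(
    cohort: Cohort,
    spec: GridSpec | None = None,
    causal_sizes: tuple[int, ...] = (1, 5, 10),
    n_bootstrap: int = 1000,
) -> pd.DataFrame:
    """AUC change from the sensitive phenotype, with bootstrap CIs.

    Re-runs the top-causal cells (k = 0, one classification replicate, all
    collapse depths) training on the sensitive collapsed status instead of
    the specific one, and summarises the per-setting AUC improvement for
    each method with a percentile bootstrap CI over the settings.
    """
    spec = (spec or GridSpec()).resolve(cohort)
    rep = spec.classification_replicate_ids[0]
    per_mode = {}
    for mode in ("specific", "sensitive"):
        sub = replace(
            spec,
            gene_lists=tuple(("causal", s) for s in causal_sizes),
            noise_levels=(0.0,),
            classification_replicate_ids=(rep,),
            phenotype_mode=mode,
        )
        per_mode[mode] = {
            (c.gene_list_size, c.m): c.auc_by_method for c in run_grid(cohort, sub)
        }
    settings = sorted(per_mode["specific"])
    rng = np.random.default_rng(derive_seed(spec.seed, "followup2-bootstrap"))
    rows = []
    for method in METHODS:
        diffs = np.array(
            [per_mode["sensitive"][s][method] - per_mode["specific"][s][method] for s in settings]
        )
        boots = rng.choice(diffs, size=(n_bootstrap, len(diffs)), replace=True).mean(axis=1)
        rows.append(
            {
                "method": method,
                "n_settings": len(diffs),
                "mean_improvement": float(diffs.mean()),
                "ci_low": float(np.percentile(boots, 2.5)),
                "ci_high": float(np.percentile(boots, 97.5)),
            }
        )
    return pd.DataFrame(rows).set_index("method")
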