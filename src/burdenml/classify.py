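"""Classifiers and AUC scoring.

Three probabilistic classifiers of case status from a shared design matrix:

* ``logistic`` — unpenalised maximum-likelihood logistic regression on the
  full training set (ridge-stabilised fallback when the design is wider than
  it is tall or the ML fit fails);
* ``svm_linear`` / ``svm_radial`` — support-vector machines with features
  standardised to training mean/SD, hyperparameters (C, and kernel width
  gamma for the radial kernel) tuned by seeded stratified 10-fold
  cross-validated accuracy, and Platt-style sigmoid probability calibration.

AUC is the Wilcoxon–Mann–Whitney probability that a random case outscores a
random control, ties counted one half.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import DesignMatrix
from .phenotypes import CollapsedPhenotype

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "FittedClassifier",
    "PredictionResult",
    "fit_classifier",
    "predict_scores",
    "compute_auc",
    "METHODS",
]

METHODS = ("logistic", "svm_linear", "svm_radial")

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0)

# libsvm can oscillate for ages at large C on non-separable data; a generous
# iteration cap changes the decision function negligibly at these sizes
SVM_MAX_ITER = 50_000


@dataclass
class ClassifierSpec:
    """Which classifier to fit and how to tune it."""

    method: str = "logistic"
    tuning_grid: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"C": DEFAULT_C_GRID, "gamma": DEFAULT_GAMMA_GRID}
    )
    cv_folds: int = 10
    probability_output: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.method.startswith("svm") and not self.tuning_grid.get("C"):
            raise ValueError("SVM methods need a non-empty C grid")
        if self.method == "svm_radial" and not self.tuning_grid.get("gamma"):
            raise ValueError("radial SVM needs a non-empty gamma grid")


@dataclass
class FittedClassifier:
    method: str
    columns: list[str]
    hyperparameters: dict[str, float]
    _predict: object  # callable(ndarray) -> probability vector

    def predict_scores(self, design: DesignMatrix) -> pd.Series:
        return predict_scores(self, design)


@dataclass
class PredictionResult:
    scores: pd.Series
    truth: pd.Series
    auc: float
    method: str
    fitted_hyperparameters: dict[str, float]


def _as_status(phenotype: CollapsedPhenotype | pd.Series) -> pd.Series:
    if isinstance(phenotype, CollapsedPhenotype):
        return phenotype.status
    return phenotype


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[object, dict[str, float]]:
    # design already carries an intercept column, so fit_intercept is off
    n, p = X.shape
    if p >= n:
        logger.warning("design has %d columns for %d rows; ridge-stabilised fit", p, n)
        model = LogisticRegression(penalty="l2", C=1.0, fit_intercept=False, max_iter=2000)
        model.fit(X, y)
        return model.coef_.ravel(), {"ridge_C": 1.0}
    model = LogisticRegression(
        penalty=None, solver="lbfgs", fit_intercept=False, max_iter=5000, tol=1e-9
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    beta = model.coef_.ravel()
    if not np.all(np.isfinite(beta)):
        logger.warning("maximum-likelihood logistic fit diverged; ridge-stabilised fallback")
        fb = LogisticRegression(penalty="l2", C=1.0, fit_intercept=False, max_iter=2000)
        fb.fit(X, y)
        return fb.coef_.ravel(), {"ridge_C": 1.0}
    return beta, {}


def _tune_svm(X: np.ndarray, y: np.ndarray, kernel: str, spec: ClassifierSpec) -> dict:
    """Grid-search (C, gamma) by seeded stratified k-fold CV accuracy.

    Folds are split and standardised once (training-fold mean/SD applied to
    the held-out fold) and reused for every candidate; ties resolve to the
    smallest C, then the smallest gamma.
    """
    gammas_all = sorted(spec.tuning_grid["gamma"]) if kernel == "rbf" else [None]
    cs_all = sorted(spec.tuning_grid["C"])
    if len(cs_all) == 1 and len(gammas_all) == 1:  # nothing to tune
        hyper = {"C": float(cs_all[0])}
        if kernel == "rbf":
            hyper["gamma"] = float(gammas_all[0])
        return hyper
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = []
    for tr, te in cv.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        folds.append((scaler.transform(X[tr]), scaler.transform(X[te]), y[tr], y[te]))
    best_acc, best = -1.0, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for C in cs_all:
            for gamma in gammas_all:
                acc = 0.0
                for Xtr, Xte, ytr, yte in folds:
                    svc = SVC(
                        kernel=kernel,
                        C=C,
                        gamma=gamma if gamma is not None else "scale",
                        max_iter=SVM_MAX_ITER,
                    )
                    svc.fit(Xtr, ytr)
                    acc += (svc.predict(Xte) == yte).mean()
                acc /= len(folds)
                if acc > best_acc + 1e-12:  # strict: first (smallest) wins ties
                    best_acc, best = acc, (C, gamma)
    hyper = {"C": float(best[0])}
    if kernel == "rbf":
        hyper["gamma"] = float(best[1])
    return hyper


def fit_classifier(
    design: DesignMatrix,
    phenotype: CollapsedPhenotype | pd.Series,
    spec: ClassifierSpec,
) -> FittedClassifier:
    """Fit one classifier on the selection-stage design and phenotype.

    Logistic regression is fit once by maximum likelihood on the full set.
    SVMs grid-search (C, gamma) by stratified 10-fold cross-validated
    accuracy with seeded folds (ties resolve to the smallest C, then the
    smallest gamma), then refit at the best setting with sigmoid probability
    calibration.
    """
    spec.validate()
    y = np.asarray(_as_status(phenotype), dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("phenotype has a single class; cannot fit a classifier")
    if len(_as_status(phenotype)) != design.frame.shape[0]:
        raise ValueError("design and phenotype differ on the individual axis")

    if spec.method == "logistic":
        X = design.values
        beta, hyper = _fit_logistic(X, y)

        def _predict(Xnew: np.ndarray, beta=beta) -> np.ndarray:
            return expit(Xnew @ beta)

        return FittedClassifier(spec.method, design.columns, hyper, _predict)

    # SVM: drop the intercept column (SVC has its own offset), standardise
    feat_cols = [c for c in design.columns if c != "intercept"]
    idx = [design.columns.index(c) for c in feat_cols]
    X = design.values[:, idx]
    kernel = "linear" if spec.method == "svm_linear" else "rbf"
    hyper = _tune_svm(X, y, kernel, spec)
    final = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel=kernel,
                    C=hyper["C"],
                    gamma=hyper.get("gamma", "scale"),
                    max_iter=SVM_MAX_ITER,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
        # Platt sigmoid calibration fitted within training: a logistic map of
        # the training decision values onto probabilities.  The map is
        # monotone, so ranking metrics (AUC) coincide exactly with the raw
        # decision function
        decision = final.decision_function(X).reshape(-1, 1)
        platt = LogisticRegression(C=1e6, max_iter=1000)
        platt.fit(decision, y)
    case_col = int(np.where(platt.classes_ == 1)[0][0])

    def _predict(
        Xnew: np.ndarray, final=final, platt=platt, idx=idx, case_col=case_col
    ) -> np.ndarray:
        d = final.decision_function(Xnew[:, idx]).reshape(-1, 1)
        return platt.predict_proba(d)[:, case_col]

    return FittedClassifier(spec.method, design.columns, hyper, _predict)


def predict_scores(model: FittedClassifier, design: DesignMatrix) -> pd.Series:
    """Per-individual case probability on a new design.

    The classification design must carry exactly the training columns in the
    same order; a mismatch raises with the symmetric difference listed.
    """
    if design.columns != model.columns:
        diff = sorted(set(design.columns) ^ set(model.columns))
        raise ValueError(
            f"design columns differ from training columns "
            f"(symmetric difference: {diff or 'same names, different order'})"
        )
    scores = np.clip(model._predict(design.values), 0.0, 1.0)
    return pd.Series(scores, index=design.frame.index, name="score")


def compute_auc(scores, truth) -> float:
    """Wilcoxon–Mann–Whitney AUC: P(case score > control score) + 0.5 P(tie).

    Computed from mid-ranks, which is exactly the mean over all case–control
    pairs of 1 / 0.5 / 0 for win / tie / loss.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth)
    if not np.isin(t, (0, 1)).all():
        raise ValueError("truth must be binary")
    n1 = int(t.sum())
    n0 = len(t) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one case and one control")
    ranks = rankdata(s, method="average")
    return float((ranks[t == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate(
    model: FittedClassifier, design: DesignMatrix, truth: pd.Series
) -> PredictionResult:
    """Predict on a classification design and score against held-out status."""
    scores = predict_scores(model, design)
    truth = truth.loc[scores.index]
    return PredictionResult(
        scores=scores,
        truth=truth,
        auc=compute_auc(scores, truth),
        method=model.method,
        fitted_hyperparameters=model.hyperparameters,
    )
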