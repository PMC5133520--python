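"""Per-gene association testing and top-gene list construction.

Each candidate gene is scored by a joint likelihood-ratio test of its term
block (expression G, burden S, interaction G*S — or S alone when expression
is excluded) against the nested covariates-only model, with degrees of
freedom equal to the number of gene columns that survive constant-column
dropping.  Genes are then ranked by ascending p-value to form the causal /
non-causal candidate lists fed to the classifiers.

The likelihood is Firth's Jeffreys-prior-penalised logistic likelihood, and
the null model is the profile fit with the gene coefficients constrained to
zero under the full model's penalty.  Two properties motivate this over the
plain maximum-likelihood ratio: the penalised estimate stays finite under
the (quasi-)separation that case-free pedigree indicators routinely produce
at ~10 % prevalence, and the test's null distribution is far closer to its
nominal chi-square when the tested block contains a sparse carrier indicator
and its interaction — the plain LRT is visibly anticonservative at a few
hundred cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .cohort import Cohort
from .features import DEFAULT_MAF_THRESHOLD, DesignMatrix, build_design, in_sample_maf
from .phenotypes import CollapsedPhenotype

logger = logging.getLogger(__name__)

__all__ = ["GeneTestResult", "GeneList", "gene_pvalue", "rank_genes", "select_top_genes"]

MAXITER = 80
PLL_TOL = 1e-9


@dataclass
class GeneTestResult:
    gene_id: str
    p_value: float
    test_df: int
    converged: bool
    is_causal: bool | None  # None when truth is unknown


@dataclass
class GeneList:
    gene_ids: list[str]
    list_kind: str  # causal | noncausal | any
    size: int


def _penalised_ll(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    mu = expit(X @ beta)
    ll = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    w = np.clip(mu * (1 - mu), 1e-12, None)
    _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    return ll + 0.5 * logdet


def _firth_profile_pll(y: np.ndarray, X: np.ndarray, n_free: int) -> float | None:
    """Maximised Firth penalised log-likelihood with trailing columns fixed at 0.

    The first ``n_free`` coefficients are free; the rest are constrained to
    zero but still enter the Jeffreys penalty through the full-design
    information matrix, which is what makes the constrained and unconstrained
    maxima comparable in a penalised likelihood-ratio statistic.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pll = -np.inf
    try:
        for _ in range(MAXITER):
            mu = expit(X @ beta)
            w = np.clip(mu * (1 - mu), 1e-12, None)
            sw = np.sqrt(w)
            info = X.T @ (X * w[:, None])
            info_inv = np.linalg.pinv(info, rcond=1e-12)
            Xs = X * sw[:, None]
            hat = np.einsum("ij,jk,ik->i", Xs, info_inv, Xs)
            score = X.T @ (y - mu + hat * (0.5 - mu))
            step = np.zeros(p)
            step[:n_free] = np.linalg.pinv(info[:n_free, :n_free], rcond=1e-12) @ score[:n_free]
            lam = 1.0
            for _ in range(12):  # step-halving keeps the penalised ll ascending
                new = _penalised_ll(y, X, beta + lam * step)
                if new >= pll - 1e-12:
                    break
                lam /= 2
            beta = beta + lam * step
            if abs(new - pll) < PLL_TOL:
                return float(new)
            pll = new
    except np.linalg.LinAlgError as exc:
        logger.debug("Firth fit failed: %s", exc)
        return None
    return float(pll)  # iteration cap hit: plateau value is still usable


def gene_pvalue(
    design: DesignMatrix,
    phenotype: CollapsedPhenotype | pd.Series,
    gene_id: str | None = None,
    is_causal: bool | None = None,
) -> GeneTestResult:
    """Penalised joint LRT of one gene's term block vs the covariates-only model.

    A failed fit never raises: the gene is reported with ``p_value = 1`` and
    ``converged = False`` so it ranks last.  A gene whose columns were all
    dropped as constant gets p = 1 with df = 0.
    """
    y = (phenotype.status if isinstance(phenotype, CollapsedPhenotype) else phenotype)
    y = np.asarray(y, dtype=float)
    gene_cols = design.gene_columns(gene_id)
    gid = gene_id or (gene_cols[0].rsplit("_", 1)[0] if gene_cols else "<none>")
    df = len(gene_cols)
    if df == 0:
        return GeneTestResult(gid, 1.0, 0, True, is_causal)
    # column order is covariates first, gene terms last
    ordered = [c for c in design.columns if c not in gene_cols] + gene_cols
    X = design.frame[ordered].to_numpy(dtype=float)
    n_nuisance = X.shape[1] - df
    full = _firth_profile_pll(y, X, X.shape[1])
    null = _firth_profile_pll(y, X, n_nuisance)
    if full is None or null is None:
        logger.warning("gene %s: penalised fit failed; p set to 1", gid)
        return GeneTestResult(gid, 1.0, df, False, is_causal)
    lr = max(0.0, 2.0 * (full - null))
    return GeneTestResult(gid, float(chi2.sf(lr, df)), df, True, is_causal)


def rank_genes(
    cohort: Cohort,
    phenotype: CollapsedPhenotype,
    gene_ids: list[str] | None = None,
    include_expression: bool = True,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    expression: pd.DataFrame | None = None,
) -> list[GeneTestResult]:
    """Per-gene penalised LRT p-values against one collapsed phenotype.

    The null fit is the profile fit under each gene's own design (its penalty
    involves the gene columns), so there is no shared null model across
    genes.  ``expression`` may carry the noise-perturbed selection-stage
    matrix.  Returns results in the input gene order (unsorted).
    """
    if gene_ids is None:
        gene_ids = cohort.gene_ids
    maf = in_sample_maf(cohort.genotypes)
    causal_known = len(cohort.causal_genes) > 0
    results = []
    for gid in gene_ids:
        design = build_design(
            cohort,
            [gid],
            include_expression=include_expression,
            maf_threshold=maf_threshold,
            expression=expression,
            maf=maf,
        )
        results.append(
            gene_pvalue(
                design,
                phenotype,
                gene_id=gid,
                is_causal=(gid in cohort.causal_genes) if causal_known else None,
            )
        )
    return results


def select_top_genes(
    results: list[GeneTestResult], list_kind: str, size: int
) -> GeneList:
    """Smallest-p genes of the requested kind; ties broken lexicographically.

    ``list_kind`` is ``causal``, ``noncausal`` (both need causal labels) or
    ``any``.  Sorting is by (p_value, gene_id), so the output is stable under
    permutation of the input and idempotent.
    """
    if not results:
        raise ValueError("empty result list")
    if list_kind == "causal":
        pool = [r for r in results if r.is_causal is True]
    elif list_kind == "noncausal":
        pool = [r for r in results if r.is_causal is False]
    elif list_kind == "any":
        pool = list(results)
    else:
        raise ValueError(f"unknown list kind {list_kind!r}")
    if list_kind != "any" and any(r.is_causal is None for r in results):
        raise ValueError("causal labels unavailable for this cohort")
    if size > len(pool):
        raise ValueError(f"requested {size} {list_kind} genes, only {len(pool)} available")
    ordered = sorted(pool, key=lambda r: (r.p_value, r.gene_id))
    return GeneList(gene_ids=[r.gene_id for r in ordered[:size]], list_kind=list_kind, size=size)


def results_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    """Ranked-gene table (ascending p) for CSV export."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "p_value": [r.p_value for r in results],
            "df": [r.test_df for r in results],
            "converged": [r.converged for r in results],
            "is_causal": [r.is_causal for r in results],
        }
    )
    return df.sort_values(["p_value", "gene_id"], kind="mergesort").reset_index(drop=True)
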