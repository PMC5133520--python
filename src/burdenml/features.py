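"""Per-gene predictors and the design matrix.

For each gene the model uses three terms: the rare-variant burden indicator
S (1 when an individual carries any minor allele at any variant of the gene
with in-sample MAF below the threshold, 0.05 by default — the "collapsing"
of combined multivariate and collapsing), the continuous expression level G,
and their product G*S.  Covariates enter as age, sex, smoking, an age-by-sex
product, and one indicator per non-reference pedigree.

Also implements the expression-noise perturbation: independent
Uniform(-k, k) noise added entrywise to an expression matrix, applied by the
caller to selection-stage data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeatures",
    "DesignMatrix",
    "in_sample_maf",
    "minor_allele_counts",
    "compute_burden",
    "gene_features",
    "inject_expression_noise",
    "build_design",
]

DEFAULT_MAF_THRESHOLD = 0.05


def in_sample_maf(genotypes: pd.DataFrame) -> pd.Series:
    """Minor allele frequency of every variant from the loaded sample itself.

    The coded-allele frequency is count-sum / 2n; the minor allele is
    whichever is less frequent in-sample, so the result is always <= 0.5.
    """
    freq = genotypes.mean(axis=0) / 2.0
    return pd.concat([freq, 1.0 - freq], axis=1).min(axis=1).rename("maf")


def minor_allele_counts(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Re-orient counts so every column counts its in-sample minor allele."""
    freq = genotypes.mean(axis=0) / 2.0
    flip = freq > 0.5
    out = genotypes.copy()
    if flip.any():
        out.loc[:, flip] = 2 - out.loc[:, flip]
    return out


@dataclass
class GeneFeatures:
    """The three per-gene predictors, on a shared individual axis."""

    gene_id: str
    burden: pd.Series       # S: binary carrier indicator
    expression: pd.Series   # G: continuous expression level
    interaction: pd.Series  # G * S, elementwise
    maf_threshold: float = DEFAULT_MAF_THRESHOLD


def compute_burden(
    cohort: Cohort,
    gene_id: str,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    maf: pd.Series | None = None,
) -> pd.Series:
    """Carrier indicator: any minor allele at any rare variant of the gene.

    Variants with MAF >= ``maf_threshold`` are ignored (strict inequality).
    ``maf`` may supply precomputed per-variant frequencies (e.g. cached
    in-sample values); by default they are recomputed from the cohort's
    genotype matrix.
    """
    variants = cohort.variants_of(gene_id)
    block = cohort.genotypes[variants]
    if maf is None:
        maf = in_sample_maf(cohort.genotypes)
    rare = [v for v in variants if maf[v] < maf_threshold]
    if not rare:
        return pd.Series(0, index=cohort.individuals, dtype=np.int8, name=f"{gene_id}_S")
    counts = minor_allele_counts(block[rare])
    return (counts > 0).any(axis=1).astype(np.int8).rename(f"{gene_id}_S")


def gene_features(
    cohort: Cohort,
    gene_id: str,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    expression: pd.DataFrame | None = None,
    maf: pd.Series | None = None,
) -> GeneFeatures:
    """Assemble S, G and G*S for one gene (optionally with perturbed expression)."""
    expr = cohort.expression if expression is None else expression
    if gene_id not in expr.columns:
        raise KeyError(f"gene {gene_id!r} absent from expression table")
    s = compute_burden(cohort, gene_id, maf_threshold, maf=maf)
    g = expr[gene_id].rename(f"{gene_id}_G")
    return GeneFeatures(
        gene_id=gene_id,
        burden=s,
        expression=g,
        interaction=(g * s).rename(f"{gene_id}_GxS"),
        maf_threshold=maf_threshold,
    )


def inject_expression_noise(
    expression: pd.DataFrame, k: float, seed: int
) -> pd.DataFrame:
    """Perturb every expression entry by an independent Uniform(-k, k) draw.

    ``k = 0`` returns the input unchanged (same object contents, new frame).
    By contract this is applied to selection-stage expression only; the
    classification-stage expression is never perturbed.
    """
    if k < 0:
        raise ValueError(f"noise half-width k must be >= 0, got {k}")
    if k == 0:
        return expression.copy()
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-k, k, size=expression.shape)
    return expression + noise


@dataclass
class DesignMatrix:
    """Named design matrix with per-column roles.

    ``roles`` maps each column to one of ``covariate`` (including the
    intercept), ``pedigree`` or ``gene_term``; ``dropped_columns`` lists
    gene-term columns removed because they were constant in this cohort.
    """

    frame: pd.DataFrame
    roles: dict[str, str]
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    include_expression: bool = True
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def gene_columns(self, gene_id: str | None = None) -> list[str]:
        cols = [c for c, r in self.roles.items() if r == "gene_term" and c in self.frame.columns]
        if gene_id is not None:
            cols = [c for c in cols if c.startswith(f"{gene_id}_")]
        return cols

    def covariate_frame(self) -> pd.DataFrame:
        keep = [c for c in self.frame.columns if self.roles[c] != "gene_term"]
        return self.frame[keep]


def _covariate_block(cohort: Cohort, center_age: bool, min_pedigree_size: int) -> pd.DataFrame:
    cov = cohort.covariates
    age = cov["age"].astype(float)
    if center_age:
        age = age - age.mean()
    block = pd.DataFrame(
        {
            "intercept": 1.0,
            "age": age,
            "sex": cov["sex"].astype(float),
            "smoke": cov["smoke"].astype(float),
            "age_sex": age * cov["sex"].astype(float),
        },
        index=cohort.individuals,
    )
    # pedigree indicators; reference = pedigree of the first individual in
    # ID-sorted order; small pedigrees may be merged into the reference
    ped = cov["pedigree_id"].astype(str)
    reference = ped.loc[sorted(cohort.individuals)[0]]
    sizes = ped.value_counts()
    merged = {p for p in sizes.index if sizes[p] < min_pedigree_size}
    for p in sorted(set(ped.unique()) - {reference} - merged):
        block[f"ped_{p}"] = (ped == p).astype(float)
    return block


def build_design(
    cohort: Cohort,
    gene_ids: list[str],
    include_expression: bool = True,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    expression: pd.DataFrame | None = None,
    center_age: bool = False,
    min_pedigree_size: int = 1,
    maf: pd.Series | None = None,
) -> DesignMatrix:
    """Covariate block plus, per gene, (G, S, G*S) or (S only).

    An empty ``gene_ids`` list yields the covariates-only baseline design.
    Gene-term columns that are constant in this cohort (e.g. a monomorphic
    burden) are dropped with a warning so downstream fits stay full rank.
    Column order is deterministic: covariates, then genes in the given order.
    """
    if len(gene_ids) != len(set(gene_ids)):
        raise ValueError("duplicated gene IDs in design request")
    block = _covariate_block(cohort, center_age, min_pedigree_size)
    roles = {c: ("pedigree" if c.startswith("ped_") else "covariate") for c in block.columns}
    pieces = [block]
    dropped: list[str] = []
    if maf is None:
        maf = in_sample_maf(cohort.genotypes)
    for gid in gene_ids:
        feats = gene_features(cohort, gid, maf_threshold, expression=expression, maf=maf)
        if include_expression:
            cols = [feats.expression, feats.burden.astype(float), feats.interaction]
        else:
            cols = [feats.burden.astype(float)]
        for col in cols:
            if col.nunique() <= 1:
                dropped.append(str(col.name))
                continue
            pieces.append(col.to_frame())
            roles[str(col.name)] = "gene_term"
    if dropped:
        logger.warning("dropped constant gene-term columns: %s", dropped)
    frame = pd.concat(pieces, axis=1)
    if frame.columns.duplicated().any():
        raise ValueError("duplicate column names in design")
    return DesignMatrix(
        frame=frame,
        roles=roles,
        maf_threshold=maf_threshold,
        include_expression=include_expression,
        dropped_columns=dropped,
    )
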