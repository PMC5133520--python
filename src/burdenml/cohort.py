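"""Cohort container and tab-separated / VCF ingestion.

A :class:`Cohort` bundles the four tables the pipeline consumes — genotypes
(minor-allele counts), gene expression, covariates and binary phenotype
replicates — aligned on a single individual axis, together with the
variant-to-gene annotation and (for simulated data) the set of truly causal
genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Cohort", "load_cohort", "write_cohort", "read_genotypes_vcf"]


@dataclass
class Cohort:
    """Aligned multi-omic tables for one analysis cohort.

    All tables are indexed by individual ID in the same order.  Genotype
    entries are minor-allele counts in {0, 1, 2}; phenotype replicates are
    binary columns (one per independent simulation of disease status).
    ``causal_genes`` is empty when the truth is unknown (real-data ingestion).
    ``trios`` records (child, father, mother) IDs for simulated pedigrees and
    is ``None`` for loaded cohorts.
    """

    genotypes: pd.DataFrame
    variant_annotations: pd.DataFrame  # index: variant_id; columns: gene_id, maf
    expression: pd.DataFrame
    covariates: pd.DataFrame  # columns: pedigree_id, sex, age, smoke
    phenotype_replicates: pd.DataFrame
    causal_genes: frozenset = field(default_factory=frozenset)
    trios: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.genotypes.index
        for name in ("expression", "covariates", "phenotype_replicates"):
            other = getattr(self, name).index
            if not idx.equals(other):
                raise ValueError(f"{name} index does not match genotype index")
        if not set(self.genotypes.columns) <= set(self.variant_annotations.index):
            missing = set(self.genotypes.columns) - set(self.variant_annotations.index)
            raise ValueError(f"variants missing from annotation: {sorted(missing)[:5]}")
        bad = ~self.genotypes.isin([0, 1, 2]).all(axis=0)
        if bad.any():
            raise ValueError(
                f"genotype entries outside {{0,1,2}} at variants: "
                f"{list(self.genotypes.columns[bad])[:5]}"
            )
        reps = self.phenotype_replicates
        if not reps.isin([0, 1]).all().all():
            raise ValueError("phenotype replicates must be binary")
        self.causal_genes = frozenset(self.causal_genes)

    # -- convenience accessors -------------------------------------------------

    @property
    def individuals(self) -> pd.Index:
        return self.genotypes.index

    @property
    def gene_ids(self) -> list[str]:
        """All gene IDs present in the variant annotation, sorted."""
        return sorted(self.variant_annotations["gene_id"].unique())

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes.index)

    def variants_of(self, gene_id: str) -> list[str]:
        ann = self.variant_annotations
        hits = ann.index[ann["gene_id"] == gene_id]
        if len(hits) == 0:
            raise KeyError(f"gene {gene_id!r} absent from variant annotation")
        return [v for v in self.genotypes.columns if v in set(hits)]


def _read_matrix(path: str | Path, id_col: str = "individual_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if id_col not in df.columns:
        raise ValueError(f"{path}: missing identifier column {id_col!r}")
    return df.set_index(id_col)


def load_cohort(
    genotype_path: str | Path,
    expression_path: str | Path,
    covariate_path: str | Path,
    replicate_path: str | Path,
    variant_map_path: str | Path,
) -> Cohort:
    """Load a cohort from five tab-separated files, aligning rows by ID.

    Individuals are matched across tables by identifier (sorted order), never
    by row order, so permuted files yield the identical cohort.  Missing
    genotypes are treated as 0 copies of the minor allele with a logged
    warning; any other non-{0,1,2} entry is an error naming the variant.
    """
    geno = _read_matrix(genotype_path)
    expr = _read_matrix(expression_path)
    cov = _read_matrix(covariate_path)
    reps = _read_matrix(replicate_path)

    vmap = pd.read_csv(variant_map_path, sep="\t", dtype=str)
    if "variant_id" not in vmap.columns or "gene_id" not in vmap.columns:
        raise ValueError("variant map needs columns variant_id and gene_id")
    if vmap["variant_id"].duplicated().any():
        dups = vmap.loc[vmap["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicated variant IDs in map: {dups[:5]}")
    vmap = vmap.set_index("variant_id")
    if "maf" in vmap.columns:
        vmap["maf"] = vmap["maf"].astype(float)

    if geno.columns.duplicated().any():
        dups = list(geno.columns[geno.columns.duplicated()])
        raise ValueError(f"duplicated variant IDs in genotype table: {dups[:5]}")

    ids = set(geno.index)
    for name, df in (("expression", expr), ("covariates", cov), ("replicates", reps)):
        if set(df.index) != ids:
            diff = sorted(set(df.index) ^ ids)
            raise ValueError(f"{name} identifier set differs from genotypes: {diff[:5]}")

    order = sorted(ids)
    geno = geno.loc[order]
    if geno.isna().any().any():
        n_missing = int(geno.isna().sum().sum())
        logger.warning("treating %d missing genotype entries as 0", n_missing)
        warnings.warn(f"treating {n_missing} missing genotype entries as 0")
        geno = geno.fillna(0)
    geno = geno.astype(float)
    bad_cols = geno.columns[~geno.isin([0.0, 1.0, 2.0]).all(axis=0)]
    if len(bad_cols):
        col = bad_cols[0]
        bad_vals = sorted(set(geno[col]) - {0.0, 1.0, 2.0})
        raise ValueError(f"genotype entries outside {{0,1,2}} at variant {col!r}: {bad_vals}")
    geno = geno.astype(np.int8)

    cov = cov.loc[order]
    cov["sex"] = cov["sex"].astype(int)
    cov["smoke"] = cov["smoke"].astype(int)
    cov["age"] = cov["age"].astype(float)

    return Cohort(
        genotypes=geno,
        variant_annotations=vmap,
        expression=expr.loc[order].astype(float),
        covariates=cov,
        phenotype_replicates=reps.loc[order].astype(np.int8),
        causal_genes=frozenset(),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to the five TSV files ``load_cohort`` reads.

    Returns the mapping of table name to path.  Causal-gene truth (when
    present) is written as a one-column ``causal_genes.tsv`` side file so
    simulated cohorts round-trip their labels, though ``load_cohort``
    deliberately ignores it (real-data semantics).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "expression": out / "expression.tsv",
        "covariates": out / "covariates.tsv",
        "replicates": out / "replicates.tsv",
        "variant_map": out / "variant_map.tsv",
    }
    cohort.genotypes.rename_axis("individual_id").to_csv(paths["genotypes"], sep="\t")
    cohort.expression.rename_axis("individual_id").to_csv(paths["expression"], sep="\t")
    cohort.covariates.rename_axis("individual_id").to_csv(paths["covariates"], sep="\t")
    cohort.phenotype_replicates.rename_axis("individual_id").to_csv(
        paths["replicates"], sep="\t"
    )
    cohort.variant_annotations.rename_axis("variant_id").to_csv(
        paths["variant_map"], sep="\t"
    )
    if cohort.causal_genes:
        pd.Series(sorted(cohort.causal_genes), name="gene_id").to_csv(
            out / "causal_genes.tsv", sep="\t", index=False
        )
    return paths


def read_genotypes_vcf(vcf_path: str | Path) -> pd.DataFrame:
    """Read a VCF into an individuals x variants ALT-allele-count matrix.

    Requires :mod:`cyvcf2` (optional dependency).  Counts are of the ALT
    allele; the burden machinery re-orients to the in-sample minor allele, so
    REF/ALT polarity does not matter downstream.  Missing calls count as 0.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        vid = var.ID or f"{var.CHROM}_{var.POS}_{var.REF}_{var.ALT[0]}"
        if vid in cols:
            raise ValueError(f"duplicated variant ID in VCF: {vid!r}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        counts = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=0)
        if (gt == 2).any():
            logger.warning("variant %s: %d missing calls set to 0", vid, int((gt == 2).sum()))
        cols[vid] = counts.astype(np.int8)
    return pd.DataFrame(cols, index=pd.Index(samples, name="individual_id"))
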