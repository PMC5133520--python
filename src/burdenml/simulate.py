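"""Seeded synthetic cohort generator.

Emulates the structure of a family-based sequencing study with many
independent simulated phenotype replicates over one fixed set of genotypes:
two-generation pedigrees filled by Mendelian gene-drop from founders, gene
expression optionally coupled to rare-variant burden, and a single logistic
disease model on covariates plus causal-gene burden, expression and their
interaction.  Every phenotype replicate is an independent Bernoulli draw from
that one model, so the causal variants and genotypes are identical across
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort

__all__ = ["SimulationConfig", "simulate_cohort", "DEFAULT_COVARIATE_EFFECTS"]

DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age": 0.09,      # log-odds per year; hypertension risk climbs steeply with age
    "sex": 0.5,       # male indicator
    "smoke": 0.7,     # current-smoker indicator
    "age_sex": -0.01, # age x sex product
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort and its disease model.

    Defaults mirror the emulated study design: n = 637 individuals in 20
    extended pedigrees, 200 phenotype replicates, and roughly 10 % case
    prevalence after replicate collapsing.  Effect sizes are log-odds per
    unit of the corresponding causal-gene feature.
    """

    n_individuals: int = 637
    n_pedigrees: int = 20
    n_genes: int = 100
    n_causal_genes: int = 10
    variants_per_gene: int | tuple[int, int] = (4, 16)
    maf_range: tuple[float, float] = (0.001, 0.10)
    expression_mean: float = 0.0
    expression_sd: float = 1.0
    expression_genotype_coupling: float = 0.5
    disease_intercept: float = -9.6  # calibrated to ~10 % collapsed prevalence
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    burden_effect: float = 0.8
    expression_effect: float = 0.4
    interaction_effect: float = 0.2
    n_replicates: int = 200
    founder_couples_per_pedigree: int = 4
    rare_maf_threshold: float = 0.05  # threshold defining the causal burden
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_pedigrees": self.n_pedigrees,
            "n_genes": self.n_genes,
            "n_causal_genes": self.n_causal_genes,
            "n_replicates": self.n_replicates,
            "founder_couples_per_pedigree": self.founder_couples_per_pedigree,
        }
        for name, value in counts.items():
            if int(value) != value or value < (0 if name == "n_causal_genes" else 1):
                raise ValueError(f"{name} must be a positive integer (got {value!r})")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes cannot exceed n_genes")
        if self.n_pedigrees > self.n_individuals:
            raise ValueError("n_pedigrees cannot exceed n_individuals")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5), got {self.maf_range}")
        v = self.variants_per_gene
        if isinstance(v, tuple):
            if not (1 <= v[0] <= v[1]):
                raise ValueError(f"invalid variants_per_gene range {v}")
        elif v < 1:
            raise ValueError("variants_per_gene must be >= 1")
        if self.expression_sd <= 0:
            raise ValueError("expression_sd must be positive")


def _pedigree_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort: genotypes once, then R independent phenotype replicates.

    The genotype matrix, covariates and expression are drawn a single time;
    each phenotype replicate is an independent Bernoulli draw from the same
    per-individual disease probability, mirroring a simulation study with
    fixed genotypes and many phenotype simulations.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_ped, rng_geno, rng_cov, rng_expr, rng_phen, rng_genes = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    n = config.n_individuals
    ids = [f"I{i + 1:04d}" for i in range(n)]

    # --- pedigree structure: founders + one offspring generation -------------
    sizes = _pedigree_sizes(n, config.n_pedigrees)
    pedigree_ids: list[str] = []
    founder_mask = np.zeros(n, dtype=bool)
    trio_rows: list[tuple[str, str, str]] = []
    pos = 0
    for p, size in enumerate(sizes):
        ped = f"PED{p + 1:02d}"
        members = list(range(pos, pos + size))
        pos += size
        pedigree_ids.extend([ped] * size)
        n_founders = min(2 * config.founder_couples_per_pedigree, size)
        if n_founders % 2 == 1 and n_founders < size:
            pass  # an unpaired founder simply has no offspring
        founders = members[:n_founders]
        founder_mask[founders] = True
        couples = [(founders[2 * c], founders[2 * c + 1]) for c in range(n_founders // 2)]
        for child in members[n_founders:]:
            if couples:
                fa, mo = couples[rng_ped.integers(len(couples))]
                trio_rows.append((ids[child], ids[fa], ids[mo]))
            else:  # degenerate pedigree of size 1: member is its own founder
                founder_mask[child] = True

    # --- variants and genotypes by gene-drop ---------------------------------
    v = config.variants_per_gene
    if isinstance(v, tuple):
        counts = rng_genes.integers(v[0], v[1] + 1, size=config.n_genes)
    else:
        counts = np.full(config.n_genes, v, dtype=int)
    gene_names = [f"GENE{g + 1:03d}" for g in range(config.n_genes)]
    variant_ids: list[str] = []
    variant_gene: list[str] = []
    for gname, c in zip(gene_names, counts):
        for j in range(c):
            variant_ids.append(f"{gname}_V{j + 1:02d}")
            variant_gene.append(gname)
    n_var = len(variant_ids)
    mafs = rng_genes.uniform(config.maf_range[0], config.maf_range[1], size=n_var)

    geno = np.zeros((n, n_var), dtype=np.int8)
    geno[founder_mask] = rng_geno.binomial(2, mafs, size=(int(founder_mask.sum()), n_var))
    id_pos = {iid: i for i, iid in enumerate(ids)}
    for child, fa, mo in trio_rows:  # offspring inherit one allele per parent
        gf = geno[id_pos[fa]].astype(float) / 2.0
        gm = geno[id_pos[mo]].astype(float) / 2.0
        geno[id_pos[child]] = rng_geno.binomial(1, gf) + rng_geno.binomial(1, gm)

    # --- covariates ----------------------------------------------------------
    age = rng_cov.uniform(18.0, 80.0, size=n).round(1)
    sex = rng_cov.integers(0, 2, size=n)
    smoke = (rng_cov.random(n) < 0.25).astype(int)

    # --- causal genes and generating-model features --------------------------
    causal = frozenset(
        np.asarray(gene_names)[
            rng_genes.choice(config.n_genes, size=config.n_causal_genes, replace=False)
        ]
    )
    gene_of = np.asarray(variant_gene)
    rare = mafs < config.rare_maf_threshold  # population-MAF burden definition
    burden = np.zeros((n, config.n_genes), dtype=np.int8)
    for g, gname in enumerate(gene_names):
        cols = (gene_of == gname) & rare
        if cols.any():
            burden[:, g] = (geno[:, cols] > 0).any(axis=1)

    expr = rng_expr.normal(config.expression_mean, config.expression_sd, size=(n, config.n_genes))
    expr = expr + config.expression_genotype_coupling * burden

    eta = np.full(n, config.disease_intercept, dtype=float)
    ce = config.covariate_effects
    eta += ce.get("age", 0.0) * age + ce.get("sex", 0.0) * sex + ce.get("smoke", 0.0) * smoke
    eta += ce.get("age_sex", 0.0) * age * sex
    for g, gname in enumerate(gene_names):
        if gname in causal:
            s, x = burden[:, g], expr[:, g]
            eta += config.burden_effect * s + config.expression_effect * x
            eta += config.interaction_effect * s * x
    prob = expit(eta)
    expected_cases = float(prob.sum())
    if expected_cases < 0.5 or expected_cases > n - 0.5:
        raise ValueError(
            f"degenerate disease model: expected case count {expected_cases:.3g} of {n}"
        )

    reps = rng_phen.binomial(1, prob[:, None], size=(n, config.n_replicates)).astype(np.int8)

    index = pd.Index(ids, name="individual_id")
    return Cohort(
        genotypes=pd.DataFrame(geno, index=index, columns=variant_ids),
        variant_annotations=pd.DataFrame(
            {"gene_id": variant_gene, "maf": mafs},
            index=pd.Index(variant_ids, name="variant_id"),
        ),
        expression=pd.DataFrame(expr, index=index, columns=gene_names),
        covariates=pd.DataFrame(
            {"pedigree_id": pedigree_ids, "sex": sex, "age": age, "smoke": smoke},
            index=index,
        ),
        phenotype_replicates=pd.DataFrame(
            reps,
            index=index,
            columns=[f"SIMPHEN.{r + 1}" for r in range(config.n_replicates)],
        ),
        causal_genes=causal,
        trios=pd.DataFrame(trio_rows, columns=["child", "father", "mother"]),
    )
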