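"""Synthetic cohorts with SAGE-like structure and known ground truth.

The generator emulates the statistical shape of the study cohort this
pipeline targets: ~2,717 samples (46.82% male), an ordinal 4-category
CPD phenotype with marginal proportions near 49.8/29.0/9.2/11.9% and a
male shift toward the higher categories, race and study-site
covariates, LD-blocked genotypes, and configurable gender-specific SNP
effects. Genotypes come from a Gaussian one-factor copula per gene:
two independent latent haplotypes thresholded at the MAF quantile and
summed, which gives Hardy-Weinberg-consistent dosages with
exchangeable within-gene LD and exact MAF control.

CPD categories are assigned by gender-specific thresholds on a latent
liability (covariate effects + per-allele genetic effects + standard
normal noise). The gender shift is produced through the thresholds,
not a liability main effect, so heterogeneity of *genetic* effects
stays cleanly separable from mean gender differences. Every causal
choice is recorded in a ``truth`` dict that no pipeline stage reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CohortTable, GeneAnnotation, GenotypeMatrix, ValidationError, VariantRecord

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_cohort",
    "make_fixture_suite",
]

# observed study structure used as generator defaults
CPD_MARGINALS = (0.4980, 0.2904, 0.0924, 0.1192)
CPD_GIVEN_MALE = (484 / 1272, 435 / 1272, 157 / 1272, 196 / 1272)
CPD_GIVEN_FEMALE = (869 / 1445, 354 / 1445, 94 / 1445, 128 / 1445)
MALE_FRACTION = 1272 / 2717
SITE_PROPORTIONS = {"COGA": 898 / 2717, "COGEND": 1263 / 2717, "FSCD": 556 / 2717}
CAUCASIAN_FRACTION = 1910 / 2717

_PHENO_SEED_OFFSET = 104_729  # fixed offset: phenotype stream independent of genotypes


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_samples: int = 2717
    male_fraction: float = MALE_FRACTION
    n_genes: int = 26
    snps_per_gene: int = 30
    ld_block_correlation: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal: dict[str, tuple[float, float]] = field(default_factory=dict)
    causal_snps_per_gene: int = 1
    cpd_marginals: tuple[float, float, float, float] = CPD_MARGINALS
    cpd_marginals_male: tuple[float, ...] | None = None
    cpd_marginals_female: tuple[float, ...] | None = None
    gender_cpd_shift: bool = True
    race_effect: float = 0.2
    site_effects: dict[str, float] = field(
        default_factory=lambda: {"COGA": 0.0, "COGEND": -0.3, "FSCD": 0.1})
    age_effect: float = 0.0
    missing_rate: float = 0.0
    n_hwe_violations: int = 0
    duplicate_first_snp: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cpd_marginals) - 1.0) > 1e-6:
            raise ValidationError("cpd_marginals must sum to 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValidationError("missing_rate must lie in [0, 0.5)")
        if not (0.0 <= self.ld_block_correlation < 1.0):
            raise ValidationError("ld_block_correlation must lie in [0, 1) "
                                  "(one-factor exchangeable blocks)")

    def gender_targets(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-gender CPD category targets (male, female)."""
        if self.cpd_marginals_male is not None and self.cpd_marginals_female is not None:
            return (np.asarray(self.cpd_marginals_male, dtype=float),
                    np.asarray(self.cpd_marginals_female, dtype=float))
        if self.gender_cpd_shift:
            return np.asarray(CPD_GIVEN_MALE), np.asarray(CPD_GIVEN_FEMALE)
        m = np.asarray(self.cpd_marginals, dtype=float)
        return m, m


@dataclass
class SimulatedCohort:
    """Generated data plus the ground-truth record (never read by the
    pipeline; used only to validate it)."""

    genotype: GenotypeMatrix
    cohort: CohortTable
    annotation: list[GeneAnnotation]
    truth: dict


def _gene_name(g: int) -> str:
    return f"GENE{g + 1:02d}"


def simulate_genotypes(
    config: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, list[GeneAnnotation], dict]:
    """Draw the LD-blocked dosage matrix and its gene annotation.

    Returns (GenotypeMatrix, annotation, truth) where truth records the
    target MAFs, causal SNP ids, and any injected HWE violations or
    duplicated (complete-LD) columns.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    n = config.n_samples
    rho = config.ld_block_correlation
    spacing = 500
    window = 2_000_000

    columns: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    annotation: list[GeneAnnotation] = []
    target_mafs: dict[str, float] = {}
    causal_snps: dict[str, list[str]] = {}

    for g in range(config.n_genes):
        gene = _gene_name(g)
        chrom = str(1 + g % 22)
        start = 1_000_000 + window * g
        m = config.snps_per_gene
        mafs = rng.uniform(*config.maf_range, size=m)
        dosage = np.zeros((n, m))
        for _hap in range(2):
            factor = rng.standard_normal(n)
            eps = rng.standard_normal((n, m))
            latent = np.sqrt(rho) * factor[:, None] + np.sqrt(1.0 - rho) * eps
            dosage += latent < norm.ppf(mafs)[None, :]
        ids = [f"{gene}_snp{j + 1}" for j in range(m)]
        for j, vid in enumerate(ids):
            columns.append(dosage[:, j])
            variants.append(VariantRecord(chrom=chrom, pos=start + j * spacing, id=vid,
                                          ref_allele="A", alt_allele="C"))
            target_mafs[vid] = float(mafs[j])
        annotation.append(GeneAnnotation(gene=gene, chrom=chrom, start=start,
                                         end=start + (m - 1) * spacing))
        causal_snps[gene] = ids[: config.causal_snps_per_gene]

    # duplicated columns -> complete-LD group inside gene 1
    dup_ids = []
    if config.duplicate_first_snp > 0:
        base = columns[0]
        base_var = variants[0]
        for i in range(config.duplicate_first_snp):
            vid = f"{base_var.id}_dup{i + 1}"
            columns.append(base.copy())
            variants.append(VariantRecord(chrom=base_var.chrom, pos=base_var.pos + i + 1,
                                          id=vid, ref_allele="A", alt_allele="C"))
            target_mafs[vid] = target_mafs[base_var.id]
            dup_ids.append(vid)

    dosage = np.column_stack(columns)

    # inbreeding-style HWE violations (heterozygote deficit, F = 0.5),
    # injected at common frequencies so the deficit is observable
    hwe_violation_ids = []
    if config.n_hwe_violations > 0:
        F = 0.5
        n_markers = len(variants)
        for j in range(n_markers - len(dup_ids) - config.n_hwe_violations,
                       n_markers - len(dup_ids)):
            p = float(rng.uniform(max(config.maf_range[0], 0.2), config.maf_range[1]))
            target_mafs[variants[j].id] = p
            probs = [(1 - p) ** 2 + F * p * (1 - p),
                     2 * p * (1 - p) * (1 - F),
                     p**2 + F * p * (1 - p)]
            dosage[:, j] = rng.choice([0.0, 1.0, 2.0], size=n, p=probs)
            hwe_violation_ids.append(variants[j].id)

    mask = np.zeros(dosage.shape, dtype=bool)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate

    # sampling noise near a 0.5 target can push the realized frequency
    # past 0.5; fold those columns so the counted allele stays minor
    obs = np.where(mask, np.nan, dosage)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(obs, axis=0) / 2.0
    flip = freq > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]

    samples = [f"S{i + 1:05d}" for i in range(n)]
    G = GenotypeMatrix(samples, variants, dosage, mask).with_recomputed_maf()
    truth = {
        "target_mafs": target_mafs,
        "causal_snps": causal_snps,
        "hwe_violation_ids": hwe_violation_ids,
        "complete_ld_duplicates": dup_ids,
        "ld_block_correlation": rho,
    }
    return G, annotation, truth


def simulate_phenotype(
    G: GenotypeMatrix,
    config: SimulationConfig,
    seed: int | None = None,
    truth: dict | None = None,
) -> tuple[CohortTable, dict]:
    """Assign gender/race/site/age and the ordinal CPD category.

    The latent liability is covariate effects + sum over causal genes
    of dosage x (beta_male or beta_female, per allele copy) + N(0, 1)
    noise; gender-specific thresholds are placed at Gaussian quantiles
    of the within-gender liability so realized category frequencies hit
    the per-gender targets up to Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    n = G.n_samples
    n_male = int(round(n * config.male_fraction))
    gender = np.ones(n, dtype=int)
    gender[:n_male] = 0
    rng.shuffle(gender)

    race = np.where(rng.random(n) < CAUCASIAN_FRACTION, "Caucasian", "African-American")
    sites = list(SITE_PROPORTIONS)
    site = rng.choice(sites, size=n, p=[SITE_PROPORTIONS[s] for s in sites])
    age = np.clip(rng.normal(38.7, 10.0, size=n), 18.0, 80.0)

    liability = rng.standard_normal(n)
    liability += config.race_effect * (race == "African-American")
    liability += np.array([config.site_effects.get(s, 0.0) for s in site])
    liability += config.age_effect * (age - age.mean())

    causal_used: dict[str, dict] = {}
    if config.causal:
        causal_map = (truth or {}).get("causal_snps") or {
            gene: [f"{gene}_snp{j + 1}" for j in range(config.causal_snps_per_gene)]
            for gene in config.causal
        }
        for gene, (beta_m, beta_f) in config.causal.items():
            for snp in causal_map.get(gene, []):
                dose = G.dosage[:, G.variant_index(snp)]
                beta = np.where(gender == 0, beta_m, beta_f)
                liability += beta * dose
                causal_used[snp] = {"beta_male": float(beta_m), "beta_female": float(beta_f)}

    target_m, target_f = config.gender_targets()
    cpd = np.zeros(n, dtype=int)
    thresholds: dict[str, list[float]] = {}
    for code, targets, label in ((0, target_m, "male"), (1, target_f, "female")):
        from scipy.stats import norm

        idx = gender == code
        if idx.sum() == 0:
            continue
        mu, sd = liability[idx].mean(), liability[idx].std(ddof=0)
        cum = np.cumsum(targets)[:-1]
        cuts = mu + sd * norm.ppf(cum)
        cpd[idx] = np.searchsorted(cuts, liability[idx], side="right")
        thresholds[label] = [float(c) for c in cuts]

    table = pd.DataFrame({
        "sample_id": G.samples,
        "cpd": cpd,
        "gender": gender,
        "race": race,
        "site": site,
        "age": np.round(age, 1),
    })
    truth_pheno = {
        "causal_effects": causal_used,
        "thresholds": thresholds,
        "gender_targets": {"male": [float(t) for t in target_m],
                           "female": [float(t) for t in target_f]},
    }
    return CohortTable(table), truth_pheno


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SimulatedCohort:
    """Full draw: genotypes, annotation, phenotype, and the truth record.

    The phenotype stream uses the master seed plus a fixed offset so
    the two stages are independently reproducible.
    """
    geno_seed = None if seed is None else seed % (2**31 - 1)
    pheno_seed = None if seed is None else (seed + _PHENO_SEED_OFFSET) % (2**31 - 1)
    G, annotation, truth_geno = simulate_genotypes(config, seed=geno_seed)
    cohort, truth_pheno = simulate_phenotype(G, config, seed=pheno_seed, truth=truth_geno)
    truth = {**truth_geno, **truth_pheno, "seed": seed}
    return SimulatedCohort(genotype=G, cohort=cohort, annotation=annotation, truth=truth)


def make_fixture_suite(
    out_dir: str,
    seed: int = 0,
    n_samples: int = 400,
    n_genes: int = 3,
    snps_per_gene: int = 30,
    missing_rate: float = 0.01,
    n_hwe_violations: int = 2,
) -> dict[str, str]:
    """Write a small deterministic cohort as VCF + TSV + BED + truth YAML.

    Regeneration with the same seed is byte-identical. Returns the
    paths keyed by role.
    """
    import yaml

    from .io import write_vcf

    config = SimulationConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        snps_per_gene=snps_per_gene,
        missing_rate=missing_rate,
        n_hwe_violations=n_hwe_violations,
        causal={_gene_name(0): (0.3, 0.0)},
    )
    sim = simulate_cohort(config, seed=seed)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "phenotypes": os.path.join(out_dir, "phenotypes.tsv"),
        "genes": os.path.join(out_dir, "genes.bed"),
        "truth": os.path.join(out_dir, "truth.yaml"),
    }
    write_vcf(sim.genotype, paths["vcf"])
    sim.cohort.table.to_csv(paths["phenotypes"], sep="\t", index=False)
    with open(paths["genes"], "w") as fh:
        for ann in sim.annotation:
            # BED: 0-based half-open
            fh.write(f"{ann.chrom}\t{ann.start - 1}\t{ann.end}\t{ann.gene}\n")
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(sim.truth, fh, sort_keys=True)
    return paths
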