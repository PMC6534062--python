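"""End-to-end orchestration: covariate construction (including genotype
principal components), SNP-to-gene assembly, gene/cluster/single-locus
HWU scans with and without the gender heterogeneity weight, and
multiple-testing correction.

Every scan shares one covariate residualization (gender, race dummies,
site dummies and the top genotype PCs), so the contrast between the
heterogeneity column and the homogeneous (k = 1) column isolates the
effect of the background kernel alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CohortTable, GeneAnnotation, GenotypeMatrix, ValidationError
from .hwu import HWUResult, hwu_test
from .kernels import background_kernel, combine_weights, genetic_kernel, phenotype_residuals

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "AnalysisConfig",
    "SingleLocusScan",
    "pca_covariates",
    "build_covariates",
    "assign_snps_to_genes",
    "run_gene_scan",
    "run_cluster_scan",
    "run_single_locus_scan",
    "adjust_pvalues",
    "contingency_chi_square",
]


@dataclass
class GeneSet:
    """SNP membership of one test unit (gene or cluster)."""

    gene: str
    snp_ids: list[str]
    chrom: str

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValidationError(f"gene {self.gene}: duplicate SNP ids")


@dataclass
class AnalysisConfig:
    """Tunable choices for a scan; defaults follow the pipeline's
    standard analysis (gender heterogeneity, Davies p-values, 4 PCs)."""

    flank_bp: int = 10_000
    geno_kernel: str = "maf_centered_scaled"
    pheno_transform: str = "inverse_normal_rank"
    pvalue_method: str = "davies"
    n_perm: int = 10_000
    alpha: float = 0.05
    correction: str = "bonferroni"
    n_components: int = 4
    master_seed: int | None = None
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")

    def unit_seed(self, unit: str) -> int | None:
        if self.master_seed is None:
            return None
        import zlib

        # crc32 rather than hash(): stable across processes
        return (self.master_seed + zlib.crc32(unit.encode())) % (2**31 - 1)


def pca_covariates(G: GenotypeMatrix, n_components: int = 4) -> np.ndarray:
    """Top principal-component scores of the standardized genotypes.

    Markers are centered by twice the counted-allele frequency and
    scaled by sqrt(2p(1-p)); scores are the leading left singular
    vectors scaled by their singular values. The sign of each component
    is fixed so its largest-magnitude marker loading is positive.
    """
    if G.missing_mask.any():
        raise ValidationError("PCA requires an imputed (no-missing) matrix")
    if n_components > min(G.n_samples, G.n_variants):
        raise ValidationError("n_components exceeds matrix rank bound")
    from .kernels import standardized_dosage

    z = standardized_dosage(G, centering="maf_centered_scaled")
    z = z - z.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for c in range(n_components):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            scores[:, c] *= -1.0
    return scores


def build_covariates(
    cohort: CohortTable,
    pcs: np.ndarray | None = None,
    include_gender: bool = True,
) -> np.ndarray:
    """Design columns: gender, race dummies, site dummies, PC scores.

    Categorical levels are dummy-coded with the first level (sorted)
    as reference. Constant columns are dropped so the design stays
    full rank in single-race or single-site cohorts.
    """
    cols: list[np.ndarray] = []
    if include_gender:
        cols.append(cohort.gender)
    for cat in ("race", "site"):
        series = cohort.table[cat].astype(str)
        dummies = pd.get_dummies(series, prefix=cat, drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        for c in range(pcs.shape[1]):
            cols.append(pcs[:, c])
    if not cols:
        return np.empty((len(cohort), 0))
    X = np.column_stack(cols)
    keep = X.std(axis=0) > 1e-12
    return X[:, keep]


def assign_snps_to_genes(
    variants,
    annotation: list[GeneAnnotation],
    flank_bp: int = 10_000,
) -> list[GeneSet]:
    """Map SNPs into genes: chrom match and start-flank <= pos <= end+flank.

    The interval is closed at both ends; a SNP may fall in several
    (overlapping) genes; genes with zero SNPs are returned with an
    empty membership rather than dropped.
    """
    genesets = []
    for ann in annotation:
        flank = ann.flank_bp if ann.flank_bp else flank_bp
        lo, hi = ann.start - flank, ann.end + flank
        members = [v.id for v in variants if v.chrom == ann.chrom and lo <= v.pos <= hi]
        genesets.append(GeneSet(gene=ann.gene, snp_ids=members, chrom=ann.chrom))
    return genesets


def _scan_one_unit(
    G: GenotypeMatrix,
    unit: str,
    chrom: str,
    snp_ids: list[str],
    residuals: np.ndarray,
    k_het,
    k_ones,
    config: AnalysisConfig,
) -> tuple[HWUResult, HWUResult]:
    idx = [G.variant_index(s) for s in snp_ids]
    f = genetic_kernel(G.subset_variants(idx), centering=config.geno_kernel)
    common = dict(m=len(snp_ids), method=config.pvalue_method,
                  n_perm=config.n_perm, chrom=chrom)
    res_het = hwu_test(combine_weights(k_het, f), residuals, unit=unit,
                       heterogeneity=True, seed=config.unit_seed(unit + ":het"), **common)
    res_nohet = hwu_test(combine_weights(k_ones, f), residuals, unit=unit,
                         heterogeneity=False, seed=config.unit_seed(unit + ":nohet"), **common)
    return res_het, res_nohet


def _prepare(G: GenotypeMatrix, cohort: CohortTable, config: AnalysisConfig):
    cohort = cohort.aligned_to(G.samples)
    pcs = pca_covariates(G, config.n_components) if config.n_components > 0 else None
    X = build_covariates(cohort, pcs=pcs)
    r = phenotype_residuals(cohort, covariates=X, transform=config.pheno_transform)
    k_het = background_kernel(cohort.gender)
    k_ones = background_kernel(np.zeros(len(cohort)))
    return cohort, r, k_het, k_ones


def run_gene_scan(
    G: GenotypeMatrix,
    cohort: CohortTable,
    genesets: list[GeneSet],
    config: AnalysisConfig | None = None,
) -> list[tuple[HWUResult, HWUResult]]:
    """Gene-based HWU scan: for each gene one test with the gender
    background kernel and one with k = 1, sharing the residualization.

    Results are sorted ascending by the heterogeneity p-value.
    """
    config = config or AnalysisConfig()
    cohort, r, k_het, k_ones = _prepare(G, cohort, config)
    pairs = []
    for gs in genesets:
        if not gs.snp_ids:
            warnings.warn(f"gene {gs.gene}: no SNPs assigned; skipped")
            continue
        pairs.append(_scan_one_unit(G, gs.gene, gs.chrom, gs.snp_ids, r, k_het, k_ones, config))
    pairs.sort(key=lambda pr: pr[0].p_value)
    return pairs


def run_cluster_scan(
    G: GenotypeMatrix,
    cohort: CohortTable,
    clusters: dict[str, list[GeneSet]],
    config: AnalysisConfig | None = None,
) -> list[tuple[HWUResult, HWUResult]]:
    """Joint tests of named gene clusters (member SNP sets unioned)."""
    config = config or AnalysisConfig()
    cohort, r, k_het, k_ones = _prepare(G, cohort, config)
    pairs = []
    for name, members in clusters.items():
        snp_ids: list[str] = []
        seen = set()
        for gs in members:
            for s in gs.snp_ids:
                if s not in seen:
                    seen.add(s)
                    snp_ids.append(s)
        if not snp_ids:
            warnings.warn(f"cluster {name}: empty SNP union; skipped")
            continue
        chroms = sorted({gs.chrom for gs in members})
        pairs.append(_scan_one_unit(G, name, ",".join(chroms), snp_ids, r, k_het, k_ones, config))
    pairs.sort(key=lambda pr: pr[0].p_value)
    return pairs


@dataclass
class SingleLocusScan:
    """Per-SNP HWU results plus the scan-wide Bonferroni threshold."""

    results: list[HWUResult]
    n_snps_tested: int
    bonferroni_threshold: float


def run_single_locus_scan(
    G: GenotypeMatrix,
    cohort: CohortTable,
    snp_ids: list[str],
    config: AnalysisConfig | None = None,
    heterogeneity: bool = True,
) -> SingleLocusScan:
    """HWU applied SNP by SNP (M = 1 kernels).

    Monomorphic SNPs get p = 1 with a flag. The reported significance
    threshold is alpha divided by the number of SNPs scanned, e.g.
    0.05 / 400 = 1.25e-4 for a 400-SNP scan.
    """
    config = config or AnalysisConfig()
    cohort, r, k_het, k_ones = _prepare(G, cohort, config)
    k = k_het if heterogeneity else k_ones
    results = []
    for snp in snp_ids:
        j = G.variant_index(snp)
        chrom = G.variants[j].chrom
        col = G.dosage[:, j]
        if col.std(ddof=0) < 1e-12:
            results.append(HWUResult(unit=snp, n=len(cohort), m=1, U=0.0, p_value=1.0,
                                     method=config.pvalue_method, heterogeneity=heterogeneity,
                                     chrom=chrom, flag="monomorphic"))
            continue
        f = genetic_kernel(G.subset_variants([j]), centering=config.geno_kernel)
        results.append(hwu_test(combine_weights(k, f), r, unit=snp, m=1,
                                method=config.pvalue_method, n_perm=config.n_perm,
                                seed=config.unit_seed(snp), heterogeneity=heterogeneity,
                                chrom=chrom))
    return SingleLocusScan(
        results=results,
        n_snps_tested=len(snp_ids),
        bonferroni_threshold=config.alpha / len(snp_ids) if snp_ids else float("nan"),
    )


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni or Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh_fdr":
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_bh")[1]
    raise ValidationError(f"unknown correction {method!r}")


def contingency_chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an R x C count table
    (no continuity correction). Returns (statistic, df, p)."""
    from scipy.stats import chi2_contingency

    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValidationError("contingency table must be 2-d")
    if (table < 0).any():
        raise ValidationError("negative count in contingency table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)
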