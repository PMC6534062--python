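"""Genotype quality control: call-rate and missingness filters,
Hardy-Weinberg screening in controls, mean-dosage imputation, and a
simple pairwise-concordance relatedness screen.

The filter boundaries follow the complementary reading of the marker
and individual rules: a marker is removed when its call fraction is
strictly below the threshold (a 90/100 marker survives at 0.90), and an
individual is removed when the missing fraction strictly exceeds the
threshold (exactly 10% missing survives at 0.10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .containers import CohortTable, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "filter_markers_by_call_rate",
    "filter_individuals_by_missingness",
    "hwe_exact_test",
    "hwe_chi2_test",
    "hwe_screen",
    "impute_missing_mean",
    "relatedness_screen",
    "run_qc",
]


@dataclass
class QCReport:
    """Counts and thresholds from one pass of :func:`run_qc`."""

    markers_removed_callrate: int = 0
    individuals_removed_missing: int = 0
    markers_flagged_hwe: int = 0
    individuals_removed_related: int = 0
    thresholds: dict = field(default_factory=dict)
    removed_marker_ids: list = field(default_factory=list)
    removed_sample_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "markers_removed_callrate": self.markers_removed_callrate,
            "individuals_removed_missing": self.individuals_removed_missing,
            "markers_flagged_hwe": self.markers_flagged_hwe,
            "individuals_removed_related": self.individuals_removed_related,
            "thresholds": dict(self.thresholds),
        }

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def filter_markers_by_call_rate(
    G: GenotypeMatrix, min_call_rate: float = 0.90
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop markers whose observed-call fraction is < ``min_call_rate``."""
    if not (0.0 < min_call_rate <= 1.0):
        raise ValidationError(f"min_call_rate must be in (0, 1], got {min_call_rate}")
    if G.n_samples == 0 or G.n_variants == 0:
        raise ValidationError("empty genotype matrix")
    call_frac = 1.0 - G.missing_mask.mean(axis=0)
    keep = np.nonzero(call_frac >= min_call_rate)[0]
    removed = [G.variants[j].id for j in np.nonzero(call_frac < min_call_rate)[0]]
    return G.subset_variants(keep), removed


def filter_individuals_by_missingness(
    G: GenotypeMatrix, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals whose missing-genotype fraction is > ``max_missing``."""
    if not (0.0 <= max_missing < 1.0):
        raise ValidationError(f"max_missing must be in [0, 1), got {max_missing}")
    miss_frac = G.missing_mask.mean(axis=1)
    keep = np.nonzero(miss_frac <= max_missing)[0]
    if keep.size == 0:
        raise ValidationError("missingness filter would remove every individual")
    removed = [G.samples[i] for i in np.nonzero(miss_frac > max_missing)[0]]
    return G.subset_samples(keep), removed


def _hwe_het_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` diploids carrying ``n_minor`` copies of the rarer allele,
    P(het = h) = n! / (n_AA! n_Aa! n_aa!) * 2^h * n_a! n_A! / (2n)! over
    heterozygote counts h with the same parity as ``n_minor``.
    Returns (support, log-probabilities).
    """
    from scipy.special import gammaln

    h = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    n_aa = (n_minor - h) // 2
    n_AA = n - n_aa - h
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(h + 1)
        - gammaln(n_aa + 1)
        + h * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    return h, logp


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    The p-value sums the conditional probabilities (given the allele
    counts) of every heterozygote count whose probability does not
    exceed that of the observed count.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValidationError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise ValidationError("total genotype count is zero")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    h_obs = n_Aa
    support, logp = _hwe_het_log_probs(n, n_minor)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[support == h_obs][0]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-10)].sum()))


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Asymptotic 1-df chi-square HWE test (no continuity correction)."""
    from scipy.stats import chi2

    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative genotype count")
    n = counts.sum()
    if n == 0:
        raise ValidationError("total genotype count is zero")
    p = (2 * n_aa + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    stat = ((counts - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, df=1))


def _genotype_counts(col: np.ndarray, mask_col: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts for one marker; fractional calls are skipped."""
    obs = col[~mask_col]
    obs = obs[np.abs(obs - np.round(obs)) < 1e-9]
    g = np.round(obs).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def hwe_screen(
    G: GenotypeMatrix,
    cohort: CohortTable,
    control_rule: Callable[[CohortTable], np.ndarray] | None = None,
    alpha_hwe: float = 1e-4,
    test: str = "exact",
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove markers out of Hardy-Weinberg equilibrium in the controls.

    ``control_rule`` maps the cohort to a boolean mask; the default
    takes samples in the lowest CPD category (cpd == 0) as controls.
    """
    cohort = cohort.aligned_to(G.samples)
    if control_rule is None:
        control = cohort.cpd == 0
    else:
        control = np.asarray(control_rule(cohort), dtype=bool)
    if control.sum() == 0:
        raise ValidationError("no control samples under the control rule")
    test_fn = {"exact": hwe_exact_test, "chi2": hwe_chi2_test}[test]
    flagged: list[int] = []
    for j in range(G.n_variants):
        n0, n1, n2 = _genotype_counts(G.dosage[control, j], G.missing_mask[control, j])
        if n0 + n1 + n2 == 0:
            continue
        if alpha_hwe > 0 and test_fn(n0, n1, n2) < alpha_hwe:
            flagged.append(j)
    keep = [j for j in range(G.n_variants) if j not in set(flagged)]
    return G.subset_variants(keep), [G.variants[j].id for j in flagged]


def impute_missing_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by the marker's mean observed dosage."""
    if not G.missing_mask.any():
        return G.copy()
    n_obs = (~G.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [G.variants[j].id for j in np.nonzero(n_obs == 0)[0]]
        raise ValidationError(f"markers with zero observed calls: {bad[:5]}")
    d = np.where(G.missing_mask, 0.0, G.dosage)
    means = d.sum(axis=0) / n_obs
    dosage = np.where(G.missing_mask, means[None, :], G.dosage)
    return GenotypeMatrix(
        samples=list(G.samples),
        variants=list(G.variants),
        dosage=dosage,
        missing_mask=np.zeros_like(G.missing_mask),
    )


def relatedness_screen(
    G: GenotypeMatrix, max_concordance: float = 0.95, min_shared: int = 200
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove one member of any near-duplicate pair.

    Pairwise genotype concordance (fraction of identical hard calls over
    jointly observed markers) is a deliberately simple surrogate for
    relatedness inference: it only detects duplicates/identical twins
    and near-duplicates, not lower-degree relationships. For any pair
    sharing >= ``min_shared`` markers with concordance > threshold, the
    member with higher missingness (ties: the later sample) is removed.
    """
    if G.n_samples < 2:
        raise ValidationError("relatedness screen needs at least two individuals")
    if max_concordance >= 1.0:
        return G.copy(), []
    obs = ~G.missing_mask
    d = np.round(np.where(obs, G.dosage, -1.0)).astype(int)
    miss_count = G.missing_mask.sum(axis=1)
    removed: set[int] = set()
    n = G.n_samples
    for i in range(n):
        if i in removed:
            continue
        for k in range(i + 1, n):
            if k in removed:
                continue
            shared = obs[i] & obs[k]
            n_shared = int(shared.sum())
            if n_shared < min_shared:
                continue
            conc = float((d[i, shared] == d[k, shared]).mean())
            if conc > max_concordance:
                drop = k if miss_count[k] >= miss_count[i] else i
                removed.add(drop)
                if drop == i:
                    break
    keep = [i for i in range(n) if i not in removed]
    removed_ids = [G.samples[i] for i in sorted(removed)]
    return G.subset_samples(keep), removed_ids


def run_qc(
    G: GenotypeMatrix,
    cohort: CohortTable,
    min_call_rate: float = 0.90,
    max_missing: float = 0.10,
    alpha_hwe: float = 1e-4,
    control_rule: Callable[[CohortTable], np.ndarray] | None = None,
    relatedness_threshold: float = 1.0,
    impute: bool = True,
) -> tuple[GenotypeMatrix, CohortTable, QCReport]:
    """Full QC pass: call rate -> individual missingness -> HWE in
    controls -> relatedness -> mean imputation. Returns the filtered
    genotype matrix, the cohort aligned to it, and a report.

    The relatedness screen is off by default (threshold 1.0) because it
    is a duplicate detector, not a kinship estimate.
    """
    report = QCReport(thresholds={
        "min_call_rate": min_call_rate,
        "max_missing": max_missing,
        "alpha_hwe": alpha_hwe,
        "relatedness_threshold": relatedness_threshold,
    })
    G1, dropped_m = filter_markers_by_call_rate(G, min_call_rate)
    report.markers_removed_callrate = len(dropped_m)
    report.removed_marker_ids += dropped_m
    G2, dropped_i = filter_individuals_by_missingness(G1, max_missing)
    report.individuals_removed_missing = len(dropped_i)
    report.removed_sample_ids += dropped_i
    cohort2 = cohort.aligned_to(G2.samples)
    G3, flagged = hwe_screen(G2, cohort2, control_rule=control_rule, alpha_hwe=alpha_hwe)
    report.markers_flagged_hwe = len(flagged)
    report.removed_marker_ids += flagged
    if relatedness_threshold < 1.0:
        G4, dup = relatedness_screen(G3, max_concordance=relatedness_threshold)
        report.individuals_removed_related = len(dup)
        report.removed_sample_ids += dup
    else:
        G4 = G3
    cohort4 = cohort.aligned_to(G4.samples)
    G5 = impute_missing_mean(G4) if impute else G4
    logger.info("QC: %s", report.to_dict())
    return G5.with_recomputed_maf(), cohort4, report
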