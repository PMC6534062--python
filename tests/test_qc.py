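import math
from fractions import Fraction

import numpy as np
import pytest

from hwukit.containers import GenotypeMatrix, ValidationError, VariantRecord
from hwukit.qc import (
    filter_individuals_by_missingness,
    filter_markers_by_call_rate,
    hwe_exact_test,
    hwe_screen,
    impute_missing_mean,
    relatedness_screen,
    run_qc,
)


def _matrix(dosage, mask=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = [VariantRecord(chrom="1", pos=100 + j, id=f"snp{j}") for j in range(m)]
    samples = [f"S{i}" for i in range(n)]
    if mask is None:
        mask = np.zeros((n, m), dtype=bool)
    return GenotypeMatrix(samples, variants, dosage, mask)


class TestCallRateFilter:
    def test_boundary_strictly_less_than(self):
        # marker 0: 89/100 calls -> removed; marker 1: 90/100 -> retained
        mask = np.zeros((100, 2), dtype=bool)
        mask[:11, 0] = True
        mask[:10, 1] = True
        G = _matrix(np.ones((100, 2)), mask)
        out, removed = filter_markers_by_call_rate(G, 0.90)
        assert removed == ["snp0"]
        assert out.variant_ids == ["snp1"]

    def test_fully_observed_untouched(self):
        G = _matrix(np.ones((10, 3)))
        out, removed = filter_markers_by_call_rate(G)
        assert removed == [] and out.n_variants == 3

    def test_idempotent(self):
        mask = np.zeros((100, 3), dtype=bool)
        mask[:30, 1] = True
        G = _matrix(np.zeros((100, 3)), mask)
        once, _ = filter_markers_by_call_rate(G)
        twice, removed = filter_markers_by_call_rate(once)
        assert removed == [] and twice.variant_ids == once.variant_ids


class TestIndividualMissingness:
    def test_boundary_strictly_greater_than(self):
        # individual 0: 11/100 missing -> removed; individual 1: 10/100 -> kept
        mask = np.zeros((3, 100), dtype=bool)
        mask[0, :11] = True
        mask[1, :10] = True
        G = _matrix(np.ones((3, 100)), mask)
        out, removed = filter_individuals_by_missingness(G, 0.10)
        assert removed == ["S0"]
        assert out.samples == ["S1", "S2"]

    def test_all_removed_is_error(self):
        G = _matrix(np.ones((2, 4)), np.ones((2, 4), dtype=bool))
        with pytest.raises(ValidationError):
            filter_individuals_by_missingness(G, 0.10)


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational enumeration of the conditional heterozygote
    distribution; independent of the package implementation."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    probs = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        aa = (n_minor - h) // 2
        AA = n - aa - h
        probs[h] = (
            Fraction(math.factorial(n), math.factorial(AA) * math.factorial(h) * math.factorial(aa))
            * Fraction(2**h)
            * Fraction(math.factorial(n_minor) * math.factorial(2 * n - n_minor),
                       math.factorial(2 * n))
        )
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return float(sum(p for p in probs.values() if p / total <= p_obs) / total)


class TestHWEExact:
    def test_monomorphic_marker_p_one(self):
        assert hwe_exact_test(17, 0, 0) == 1.0

    def test_small_case_matches_enumeration(self):
        assert hwe_exact_test(1, 2, 1) == pytest.approx(hwe_enumeration_oracle(1, 2, 1), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_counts_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(1, 51))
            n_aa = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_aa + 1))
            n_AA = n - n_aa - n_Aa
            got = hwe_exact_test(n_AA, n_Aa, n_aa)
            want = hwe_enumeration_oracle(n_AA, n_Aa, n_aa)
            assert got == pytest.approx(want, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(-1, 2, 3)


class TestHWEScreen:
    def test_zero_heterozygotes_flagged(self, tiny_cohort):
        # 2 controls is too few; build a larger cohort inline
        import pandas as pd

        from hwukit.containers import CohortTable

        n = 200
        rng = np.random.default_rng(0)
        # marker 0: no heterozygotes, both homozygotes common; marker 1: HWE
        col0 = rng.choice([0.0, 2.0], size=n)
        col1 = rng.binomial(2, 0.4, size=n).astype(float)
        G = _matrix(np.column_stack([col0, col1]))
        cohort = CohortTable(pd.DataFrame({
            "sample_id": G.samples,
            "cpd": [0] * n,
            "gender": [0, 1] * (n // 2),
            "race": ["C"] * n,
            "site": ["X"] * n,
            "age": [40.0] * n,
        }))
        out, flagged = hwe_screen(G, cohort, alpha_hwe=1e-4)
        assert flagged == ["snp0"]
        assert out.variant_ids == ["snp1"]

    def test_alpha_zero_flags_nothing(self, small_cohort):
        _, flagged = hwe_screen(small_cohort.genotype, small_cohort.cohort, alpha_hwe=0.0)
        assert flagged == []

    def test_no_controls_is_error(self, small_cohort):
        with pytest.raises(ValidationError, match="control"):
            hwe_screen(small_cohort.genotype, small_cohort.cohort,
                       control_rule=lambda c: np.zeros(len(c), dtype=bool))


class TestImputation:
    def test_mean_fills_missing(self):
        mask = np.zeros((3, 1), dtype=bool)
        mask[2, 0] = True
        G = _matrix(np.array([[0.0], [2.0], [0.0]]), mask)
        out = impute_missing_mean(G)
        assert out.dosage[2, 0] == pytest.approx(1.0)
        assert not out.missing_mask.any()

    def test_identity_without_missing(self, tiny_genotypes):
        G = impute_missing_mean(impute_missing_mean(tiny_genotypes))
        assert np.allclose(G.dosage, impute_missing_mean(tiny_genotypes).dosage)

    def test_marker_means_preserved(self, small_cohort):
        G = small_cohort.genotype
        out = impute_missing_mean(G)
        obs_mean = np.array([G.dosage[~G.missing_mask[:, j], j].mean()
                             for j in range(G.n_variants)])
        assert np.allclose(out.dosage.mean(axis=0), obs_mean, atol=1e-12)


class TestRelatedness:
    def test_duplicate_sample_removed(self):
        rng = np.random.default_rng(1)
        base = rng.binomial(2, 0.3, size=(5, 250)).astype(float)
        dosage = np.vstack([base, base[0]])  # sample 5 duplicates sample 0
        G = _matrix(dosage)
        out, removed = relatedness_screen(G, max_concordance=0.95)
        assert len(removed) == 1
        assert out.n_samples == 5

    def test_unrelated_samples_survive(self):
        rng = np.random.default_rng(2)
        G = _matrix(rng.binomial(2, 0.3, size=(8, 300)).astype(float))
        _, removed = relatedness_screen(G, max_concordance=0.95)
        assert removed == []

    def test_threshold_one_is_noop(self):
        G = _matrix(np.ones((3, 5)))
        out, removed = relatedness_screen(G, max_concordance=1.0)
        assert removed == [] and out.n_samples == 3


def test_run_qc_removes_nothing_without_missingness():
    from hwukit.simulate import SimulationConfig, simulate_cohort

    sim = simulate_cohort(SimulationConfig(n_samples=200, n_genes=2,
                                           snps_per_gene=10, missing_rate=0.0),
                          seed=12)
    G, cohort, report = run_qc(sim.genotype, sim.cohort)
    assert report.markers_removed_callrate == 0
    assert report.individuals_removed_missing == 0
    assert not G.missing_mask.any()
    assert len(cohort) == G.n_samples


def test_run_qc_aligns_cohort_and_imputes(small_cohort):
    # 2% MCAR missingness: whoever survives the filters is imputed and
    # the cohort rows track the genotype samples exactly
    G, cohort, report = run_qc(small_cohort.genotype, small_cohort.cohort)
    assert not G.missing_mask.any()
    assert cohort.sample_ids == G.samples
    assert G.n_samples + report.individuals_removed_missing == 300
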