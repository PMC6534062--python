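import numpy as np
import pandas as pd
import pytest

from hwukit.containers import CohortTable, GenotypeMatrix, ValidationError, VariantRecord
from hwukit.kernels import (
    background_kernel,
    combine_weights,
    genetic_kernel,
    phenotype_residuals,
    phenotype_similarity,
)


def _geno(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        [f"S{i}" for i in range(n)],
        [VariantRecord(chrom="1", pos=100 + j, id=f"snp{j}") for j in range(m)],
        dosage,
        np.zeros((n, m), dtype=bool),
    )


def _cohort(cpd, gender):
    n = len(cpd)
    return CohortTable(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "cpd": cpd,
        "gender": gender,
        "race": ["C"] * n,
        "site": ["X"] * n,
        "age": [40.0] * n,
    }))


class TestBackgroundKernel:
    @pytest.mark.parametrize("x, expected", [([0, 0], 1.0), ([0, 1], 0.0), ([1, 1], 1.0)])
    def test_pairwise_formula(self, x, expected):
        k = background_kernel(np.array(x, dtype=float))
        assert k.values[0, 1] == pytest.approx(expected)
        assert np.allclose(np.diag(k.values), 1.0)

    def test_single_gender_is_all_ones(self):
        k = background_kernel(np.zeros(6))
        assert np.allclose(k.values, 1.0)

    def test_binary_codes_partition_into_two_cliques(self):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        x = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        k = background_kernel(x)
        n_comp, labels = connected_components(csr_matrix(k.values > 0), directed=False)
        assert n_comp == 2
        # members of a component share the gender code
        for c in range(2):
            assert len(set(x[labels == c])) == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            background_kernel(np.array([0.0, 1.5]))


class TestGeneticKernel:
    def test_single_snp_closed_form(self):
        # dosages [0, 2], p = 0.5 -> z = (g - 2p)/sqrt(2p(1-p)) = -+sqrt(2),
        # so f_12 = -2 and f_11 = +2
        f = genetic_kernel(_geno([[0], [2]]))
        assert f.values[0, 1] == pytest.approx(-2.0)
        assert f.values[0, 0] == pytest.approx(2.0)

    def test_identical_rows_have_maximal_similarity(self):
        f = genetic_kernel(_geno([[0, 1, 2], [0, 1, 2], [2, 1, 0]]))
        assert f.values[0, 0] == pytest.approx(f.values[0, 1])
        assert f.values[0, 1] == pytest.approx(f.values[1, 1])

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        f = genetic_kernel(_geno(rng.binomial(2, 0.3, size=(20, 50))))
        assert np.linalg.eigvalsh(f.values).min() >= -1e-10

    def test_invariant_to_marker_order(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, size=(15, 8)).astype(float)
        perm = rng.permutation(8)
        assert np.allclose(genetic_kernel(_geno(d)).values,
                           genetic_kernel(_geno(d[:, perm])).values)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.4, size=(12, 6)).astype(float)
        perm = rng.permutation(12)
        f = genetic_kernel(_geno(d)).values
        fp = genetic_kernel(_geno(d[perm])).values
        assert np.allclose(fp, f[np.ix_(perm, perm)])

    def test_monomorphic_only_is_degenerate(self):
        with pytest.raises(ValidationError, match="monomorphic"):
            genetic_kernel(_geno([[1, 1], [1, 1], [1, 1]]))


class TestPhenotypeSimilarity:
    def test_standardize_closed_form(self):
        cohort = _cohort([0, 0, 3, 3], [0, 0, 1, 1])
        s = phenotype_similarity(cohort, transform="standardize")
        r = s.meta["residuals"]
        assert np.allclose(r, [-1, -1, 1, 1])
        assert s.values[0, 1] == pytest.approx(1.0)
        assert s.values[0, 2] == pytest.approx(-1.0)

    def test_covariate_equal_to_phenotype_degenerates(self):
        cohort = _cohort([0, 1, 2, 3, 0, 1, 2, 3], [0] * 8)
        y = cohort.cpd
        with pytest.warns(UserWarning, match="degenerate"):
            phenotype_residuals(cohort, covariates=y[:, None], transform="identity")

    def test_tied_categories_use_average_ranks(self):
        from scipy.stats import norm, rankdata

        cpd = [0, 0, 1, 2, 3, 3, 3, 1]
        cohort = _cohort(cpd, [0] * 8)
        r = phenotype_residuals(cohort, transform="inverse_normal_rank")
        expected = norm.ppf((rankdata(cpd) - 0.375) / (len(cpd) + 0.25))
        expected = expected - expected.mean()
        expected = expected / expected.std(ddof=0)
        assert np.allclose(r, expected)

    def test_residuals_sum_to_zero_so_similarity_sums_to_zero(self, small_cohort):
        s = phenotype_similarity(small_cohort.cohort)
        assert abs(s.meta["residuals"].sum()) < 1e-8
        assert abs(s.values.sum()) < 1e-6

    def test_constant_phenotype_rejected(self):
        cohort = _cohort([2, 2, 2, 2, 2, 2], [0] * 6)
        with pytest.raises(ValidationError, match="constant"):
            phenotype_residuals(cohort, transform="standardize")


class TestCombineWeights:
    def test_all_ones_background_recovers_genetic(self):
        f = genetic_kernel(_geno([[0, 1], [1, 2], [2, 0]]))
        k = background_kernel(np.zeros(3))
        assert np.allclose(combine_weights(k, f).values, f.values)

    def test_cross_gender_pairs_zeroed(self):
        f = genetic_kernel(_geno([[0, 1], [1, 2], [2, 0], [0, 0]]))
        k = background_kernel(np.array([0.0, 1.0, 0.0, 1.0]))
        w = combine_weights(k, f)
        assert w.values[0, 1] == 0.0 and w.values[2, 3] == 0.0
        assert w.values[0, 2] == pytest.approx(f.values[0, 2])

    def test_schur_product_of_psd_is_psd(self):
        rng = np.random.default_rng(6)
        f = genetic_kernel(_geno(rng.binomial(2, 0.4, size=(25, 10))))
        k = background_kernel((rng.random(25) < 0.5).astype(float))
        w = combine_weights(k, f)
        assert np.linalg.eigvalsh(w.values).min() >= -1e-10

    def test_dimension_mismatch_rejected(self):
        f = genetic_kernel(_geno([[0, 1], [1, 2], [2, 0]]))
        k = background_kernel(np.zeros(4))
        with pytest.raises(ValidationError):
            combine_weights(k, f)
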