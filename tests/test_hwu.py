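import itertools

import numpy as np
import pytest

from hwukit.containers import SimilarityMatrix, ValidationError
from hwukit.hwu import (
    hwu_pvalue_analytic,
    hwu_pvalue_permutation,
    hwu_statistic,
    hwu_test,
    quadform_sf,
)


def _sym(values):
    return SimilarityMatrix(values=np.asarray(values, dtype=float), kind="weight")


class TestStatistic:
    def test_single_pair_closed_form(self):
        w = _sym([[0.0, 0.5], [0.5, 0.0]])
        s = _sym([[4.0, 2.0], [2.0, 4.0]])
        assert hwu_statistic(w, s) == pytest.approx(2.0)

    def test_diagonal_excluded(self):
        w = _sym([[9.0, 0.5], [0.5, 9.0]])
        s = _sym([[9.0, 2.0], [2.0, 9.0]])
        assert hwu_statistic(w, s) == pytest.approx(2.0)

    def test_gender_block_decomposition_exact(self):
        rng = np.random.default_rng(0)
        n = 40
        gender = (rng.random(n) < 0.5).astype(float)
        f = rng.standard_normal((n, n))
        f = (f + f.T) / 2
        k = 1.0 - np.abs(gender[:, None] - gender[None, :])
        r = rng.standard_normal(n)
        w = k * f
        s = np.outer(r, r)
        U = hwu_statistic(_sym(w), _sym(s))
        parts = 0.0
        for code in (0.0, 1.0):
            idx = np.nonzero(gender == code)[0]
            Wg = w[np.ix_(idx, idx)].copy()
            np.fill_diagonal(Wg, 0.0)
            parts += float(r[idx] @ Wg @ r[idx])
        assert U == pytest.approx(parts, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            hwu_statistic(_sym(np.zeros((2, 2))), _sym(np.zeros((3, 3))))


class TestQuadformSF:
    def test_symmetric_pair_at_zero_is_half(self):
        assert quadform_sf(0.0, np.array([1.5, -1.5])) == pytest.approx(0.5, abs=1e-6)

    def test_matches_monte_carlo_oracle(self):
        # n = 30 trace-free spectrum; MC oracle with 100,000 draws
        rng = np.random.default_rng(7)
        lam = rng.standard_normal(30)
        lam -= lam.mean()
        draws = rng.standard_normal((100_000, 30)) ** 2 @ lam
        for q in (0.05, 0.25, 0.5, 0.75, 0.95):
            x = float(np.quantile(draws, q))
            mc = float((draws > x).mean())
            assert quadform_sf(x, lam, "davies") == pytest.approx(mc, abs=0.02)

    def test_right_tail_monotone_in_observed_value(self):
        rng = np.random.default_rng(8)
        lam = rng.standard_normal(20)
        xs = np.linspace(-10, 10, 25)
        ps = [quadform_sf(x, lam) for x in xs]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_deep_tail_falls_back_without_error(self):
        lam = np.array([2.0, 1.0, -0.5, -0.5])
        p = quadform_sf(500.0, lam, "davies")
        assert 0 < p <= 1e-10

    def test_all_zero_eigenvalues_degenerate(self):
        with pytest.raises(ValidationError):
            quadform_sf(0.0, np.zeros(5))


class TestAnalyticPvalue:
    def test_agrees_with_liu_in_bulk(self):
        rng = np.random.default_rng(9)
        n = 80
        W = rng.standard_normal((n, n)) / 4
        W = W + W.T
        np.fill_diagonal(W, 0.0)
        r = rng.standard_normal(n)
        r /= r.std()
        p_d = hwu_pvalue_analytic(W, r, method="davies")
        p_l = hwu_pvalue_analytic(W, r, method="liu_moment")
        assert p_d == pytest.approx(p_l, abs=0.05)

    def test_block_structure_matches_dense_eigenpath(self):
        # zero cross-gender entries: block decomposition must not change p
        rng = np.random.default_rng(10)
        n = 60
        gender = (rng.random(n) < 0.5).astype(float)
        f = rng.standard_normal((n, n))
        f = (f + f.T) / 2
        W = (1.0 - np.abs(gender[:, None] - gender[None, :])) * f
        np.fill_diagonal(W, 0.0)
        r = rng.standard_normal(n)
        U = float(r @ W @ r)
        p_block = hwu_pvalue_analytic(W, r)
        p_dense = quadform_sf(U, np.linalg.eigvalsh(W))
        assert p_block == pytest.approx(p_dense, rel=1e-6)


class TestPermutation:
    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        n = 6
        W = rng.standard_normal((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        r = rng.standard_normal(n)
        U_obs = float(r @ W @ r)
        count = sum(
            float(r[list(p)] @ W @ r[list(p)]) >= U_obs - 1e-12
            for p in itertools.permutations(range(n))
        )
        expected = count / 720
        got = hwu_pvalue_permutation(W, r, exhaustive=True)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(12)
        W = rng.standard_normal((30, 30))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        r = rng.standard_normal(30)
        p1 = hwu_pvalue_permutation(W, r, n_perm=500, seed=42)
        p2 = hwu_pvalue_permutation(W, r, n_perm=500, seed=42)
        assert p1 == p2

    def test_null_pvalues_approximately_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(13)
        n = 30
        pvals = []
        for _ in range(300):
            W = rng.standard_normal((n, n)) / 4
            W = W + W.T
            np.fill_diagonal(W, 0.0)
            r = rng.standard_normal(n)
            pvals.append(hwu_pvalue_permutation(W, r, n_perm=499, seed=int(rng.integers(2**31))))
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_permutations_rejected(self):
        W = np.zeros((4, 4))
        with pytest.raises(ValidationError):
            hwu_pvalue_permutation(W, np.ones(4), n_perm=50)


class TestHWUTestWrapper:
    def test_result_fields_consistent(self):
        rng = np.random.default_rng(14)
        W = rng.standard_normal((25, 25))
        W = (W + W.T) / 2
        r = rng.standard_normal(25)
        res = hwu_test(W, r, unit="GENE", m=5, method="permutation", n_perm=200, seed=1)
        assert res.method == "permutation" and res.n_permutations == 200
        res2 = hwu_test(W, r, unit="GENE", m=5, method="davies")
        assert res2.n_permutations == 0
        assert 0 < res2.p_value <= 1
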