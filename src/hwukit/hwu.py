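"""The heterogeneity weighted U statistic and its null distribution.

The test statistic is

    U = 2 * sum_{i<j} w_ij * S_ij,

with weights ``w_ij = k_ij * f(G_i, G_j)`` and phenotypic similarity
``S_ij = r_i r_j`` built from covariate-adjusted residuals. Because S
is a residual cross-product, U is exactly the quadratic form
``r' W r`` in the (approximately standard normal) residual vector,
where W is the weight matrix with a zeroed diagonal. Under the null of
no phenotype-genotype association the distribution of U is a weighted
sum of independent 1-df chi-squares with weights the eigenvalues of W;
the tail probability is obtained by numerical inversion of the
characteristic function (the Davies/Imhof route) with a four-moment
match (Liu et al.) as fallback, and a label-permutation test serves as
the fully non-parametric oracle.

Diagonal terms are excluded from U by the classical U-statistic
convention: under the residual cross-product they only add a
data-independent offset. ``include_diagonal=True`` is available for
sensitivity analysis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import SimilarityMatrix, ValidationError

__all__ = [
    "HWUResult",
    "hwu_statistic",
    "hwu_pvalue_analytic",
    "hwu_pvalue_permutation",
    "hwu_test",
    "quadform_sf",
]

P_FLOOR = 1e-16


@dataclass
class HWUResult:
    """One HWU test: a gene, cluster or single SNP."""

    unit: str
    n: int
    m: int
    U: float
    p_value: float
    method: str
    n_permutations: int = 0
    heterogeneity: bool = True
    chrom: str | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")
        if (self.method == "permutation") != (self.n_permutations > 0):
            raise ValidationError("n_permutations > 0 iff method == 'permutation'")


def _weight_matrix(w: SimilarityMatrix | np.ndarray, include_diagonal: bool = False) -> np.ndarray:
    W = w.values if isinstance(w, SimilarityMatrix) else np.asarray(w, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10, rtol=0.0):
        raise ValidationError("weight matrix must be symmetric")
    W = W.copy()
    if not include_diagonal:
        np.fill_diagonal(W, 0.0)
    return W


def hwu_statistic(w: SimilarityMatrix, s: SimilarityMatrix) -> float:
    """U = 2 * sum_{i<j} w_ij S_ij (self-pairs excluded)."""
    if w.n != s.n:
        raise ValidationError(f"dimension mismatch: w is {w.n}, s is {s.n}")
    W = _weight_matrix(w)
    U = float(np.sum(W * s.values))
    if not math.isfinite(U):
        raise ValidationError("non-finite U statistic")
    return U


# ---------------------------------------------------------------------------
# Null distribution of a weighted chi-square mixture


def _imhof_sf(x: float, lam: np.ndarray) -> tuple[float, float]:
    """P(sum lam_h chi2_1 > x) by Imhof's characteristic-function
    inversion. Returns (probability, quadrature error estimate)."""
    from scipy.integrate import quad

    lam = np.asarray(lam, dtype=float)

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return float(np.sin(theta) * np.exp(-log_rho) / u)

    # scale of the oscillation/decay sets a practical upper limit
    scale = np.sqrt(np.sum(lam**2))
    upper = 2000.0 / max(scale, 1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        integral, abserr = quad(integrand, 1e-12, upper, limit=500)
    return 0.5 + integral / np.pi, abserr


def _liu_sf(x: float, lam: np.ndarray) -> float:
    """Four-moment match of the chi-square mixture to a shifted
    non-central chi-square (Liu, Tang & Zhang 2009)."""
    from scipy.stats import ncx2, norm

    lam = np.asarray(lam, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    if c2 <= 0:
        raise ValidationError("degenerate quadratic form (all eigenvalues ~ 0)")
    if c3 < 0:
        # negative skew: work with the negated form, P(Q > x) = 1 - P(-Q >= -x)
        return 1.0 - _liu_sf(-x, -lam)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        ell = a**2 - 2.0 * d
    else:
        if s1 <= 0:
            # symmetric: normal approximation via large df
            return float(norm.sf((x - c1) / np.sqrt(2.0 * c2)))
        ell = 1.0 / s1**2
        a = np.sqrt(ell)
        d = 0.0
    mu_q, sigma_q = c1, np.sqrt(2.0 * c2)
    mu_x, sigma_x = ell + d, np.sqrt(2.0) * a
    t = (x - mu_q) / sigma_q
    return float(ncx2.sf(t * sigma_x + mu_x, df=ell, nc=d))


def quadform_sf(x: float, lam: np.ndarray, method: str = "davies") -> float:
    """Upper-tail probability of ``sum_h lam_h chi2_{1,h}`` at ``x``.

    ``davies`` inverts the characteristic function numerically and
    falls back to the Liu moment match when the quadrature is
    unreliable (deep tails, non-convergence); ``liu_moment`` uses the
    moment match directly. The result is floored at 1e-16.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[np.abs(lam) > 1e-12 * max(np.abs(lam).max(initial=0.0), 1.0)]
    if lam.size == 0:
        raise ValidationError("degenerate quadratic form (all eigenvalues ~ 0)")
    if method == "liu_moment":
        p = _liu_sf(x, lam)
    elif method == "davies":
        p, abserr = _imhof_sf(x, lam)
        unreliable = (not math.isfinite(p)) or p <= 1e-10 or p >= 1.0 or abserr > max(1e-6, 0.1 * abs(p))
        if unreliable:
            p = _liu_sf(x, lam)
    else:
        raise ValidationError(f"unknown p-value method {method!r}")
    return float(min(1.0, max(P_FLOOR, p)))


def _eigvalsh_blocks(W: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric matrix, exploiting exact zero blocks.

    With a binary-gender background kernel the weight matrix is block
    diagonal (after an implicit permutation); decomposing per connected
    component of the sparsity graph is substantially faster and exact.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = W.shape[0]
    n_comp, labels = connected_components(csr_matrix(W != 0.0), directed=False)
    if n_comp == 1:
        return np.linalg.eigvalsh(W)
    pieces = []
    for c in range(n_comp):
        idx = np.nonzero(labels == c)[0]
        if idx.size == 1:
            pieces.append(W[idx, idx])
        else:
            pieces.append(np.linalg.eigvalsh(W[np.ix_(idx, idx)]))
    return np.concatenate(pieces)


def hwu_pvalue_analytic(
    w: SimilarityMatrix | np.ndarray,
    residuals: np.ndarray,
    method: str = "davies",
    include_diagonal: bool = False,
) -> float:
    """Right-tail p-value of U = r' W r under the quadratic-form null.

    The residuals are treated as approximately independent standard
    normals, so U is distributed as ``sum_h lam_h (chi2_1 - 1)`` with
    lam the eigenvalues of W (the centering term vanishes when the
    diagonal is zeroed, since tr W = 0).
    """
    r = np.asarray(residuals, dtype=float)
    W = _weight_matrix(w, include_diagonal=include_diagonal)
    if W.shape[0] != r.size:
        raise ValidationError("weight matrix and residual vector sizes differ")
    U = float(r @ W @ r)
    lam = _eigvalsh_blocks(W)
    return quadform_sf(U, lam, method=method)


def hwu_pvalue_permutation(
    w: SimilarityMatrix | np.ndarray,
    residuals: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    include_diagonal: bool = False,
) -> float:
    """Permutation p-value: residual labels permuted against fixed W.

    ``p = (1 + #{U_perm >= U_obs}) / (1 + n_perm)`` for Monte-Carlo
    permutations; with ``exhaustive=True`` (N <= 9) every permutation is
    enumerated once and ``p = #{U_perm >= U_obs} / N!``.
    """
    r = np.asarray(residuals, dtype=float)
    W = _weight_matrix(w, include_diagonal=include_diagonal)
    n = r.size
    if W.shape[0] != n:
        raise ValidationError("weight matrix and residual vector sizes differ")
    U_obs = float(r @ W @ r)
    if exhaustive:
        if n > 9:
            raise ValidationError("exhaustive enumeration limited to N <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = r[list(perm)]
            total += 1
            if float(rp @ W @ rp) >= U_obs - 1e-12:
                count += 1
        return count / total
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n))
        perms = np.argsort(keys, axis=1)
        R = r[perms]
        U_perm = np.einsum("bi,bi->b", R @ W, R)
        count += int(np.sum(U_perm >= U_obs - 1e-12))
        done += b
    return (1 + count) / (1 + n_perm)


def hwu_test(
    w: SimilarityMatrix | np.ndarray,
    residuals: np.ndarray,
    unit: str = "unit",
    m: int = 1,
    method: str = "davies",
    n_perm: int = 1000,
    seed: int | None = None,
    heterogeneity: bool = True,
    chrom: str | None = None,
) -> HWUResult:
    """Run one HWU test and package the result.

    ``method`` is one of {davies, liu_moment, permutation}.
    """
    r = np.asarray(residuals, dtype=float)
    W = _weight_matrix(w)
    U = float(r @ W @ r)
    if method == "permutation":
        p = hwu_pvalue_permutation(W, r, n_perm=n_perm, seed=seed)
        n_used = n_perm
    else:
        p = hwu_pvalue_analytic(W, r, method=method)
        n_used = 0
    return HWUResult(
        unit=unit,
        n=r.size,
        m=m,
        U=U,
        p_value=p,
        method=method,
        n_permutations=n_used,
        heterogeneity=heterogeneity,
        chrom=chrom,
    )
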