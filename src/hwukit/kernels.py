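"""The three similarity matrices of the HWU construction.

The heterogeneity weighted U statistic combines, for every sample pair
(i, j):

* a *background* similarity ``k_ij = 1 - |x_i - x_j|`` on a
  heterogeneity code x in [0, 1] (here gender: 0 male, 1 female), so
  same-gender pairs get weight 1 and cross-gender pairs weight 0;
* a *genetic* similarity ``f(G_i, G_j)``, the cross-product kernel of
  (by default MAF-standardized) dosage vectors; and
* a *phenotypic* similarity ``S_ij = r_i r_j``, the cross-product of
  covariate-adjusted, variance-standardized phenotype residuals.

The weight entering the U statistic is the elementwise product
``w_ij = k_ij * f(G_i, G_j)``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import CohortTable, GenotypeMatrix, SimilarityMatrix, ValidationError

__all__ = [
    "background_kernel",
    "genetic_kernel",
    "standardized_dosage",
    "phenotype_residuals",
    "phenotype_similarity",
    "combine_weights",
]


def background_kernel(x: np.ndarray) -> SimilarityMatrix:
    """Background similarity ``k_ij = 1 - |x_i - x_j|`` for codes in [0, 1].

    With binary gender codes this is the same-gender indicator: the
    induced graph has two complete components (males and females), and
    the diagonal is identically 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("heterogeneity codes must be a 1-d vector")
    if np.any((x < 0) | (x > 1)) or not np.all(np.isfinite(x)):
        raise ValidationError("heterogeneity codes must lie in [0, 1]")
    values = 1.0 - np.abs(x[:, None] - x[None, :])
    return SimilarityMatrix(values=values, kind="background", meta={"x": x.copy()})


def standardized_dosage(G: GenotypeMatrix, centering: str = "maf_centered_scaled") -> np.ndarray:
    """Per-marker centered (and optionally scaled) dosage columns.

    Under the default, column l becomes ``(g - 2 p_l) / sqrt(2 p_l (1 - p_l))``
    with ``p_l`` the counted-allele frequency. Zero-variance (monomorphic)
    columns are returned as all-zero.
    """
    if G.missing_mask.any():
        raise ValidationError("genotype matrix still has missing entries; impute first")
    d = G.dosage
    p = d.mean(axis=0) / 2.0
    if centering == "raw":
        return d.copy()
    z = d - 2.0 * p[None, :]
    if centering == "maf_centered":
        return z
    if centering != "maf_centered_scaled":
        raise ValidationError(f"unknown centering {centering!r}")
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = scale > 0
    z[:, poly] = z[:, poly] / scale[None, poly]
    z[:, ~poly] = 0.0
    return z


def genetic_kernel(G: GenotypeMatrix, centering: str = "maf_centered_scaled") -> SimilarityMatrix:
    """Cross-product genetic similarity ``f(G_i, G_j)``.

    ``f_ij = (1/M') sum_l z_il z_jl`` where M' counts the polymorphic
    markers; monomorphic markers contribute nothing and are excluded
    from the divisor. The result is Gram-form positive semi-definite.
    """
    if G.n_variants < 1:
        raise ValidationError("genetic kernel needs at least one marker")
    z = standardized_dosage(G, centering=centering)
    variances = z.var(axis=0)
    poly = variances > 1e-12
    m_eff = int(poly.sum())
    if m_eff == 0:
        raise ValidationError("all markers are monomorphic (zero variance)")
    values = (z[:, poly] @ z[:, poly].T) / m_eff
    values = (values + values.T) / 2.0
    return SimilarityMatrix(
        values=values,
        kind="genetic",
        meta={"centering": centering, "m": G.n_variants, "m_effective": m_eff},
    )


def _inverse_normal_rank(y: np.ndarray) -> np.ndarray:
    """Blom-offset rank-based inverse normal transform (ties -> average rank)."""
    from scipy.stats import norm, rankdata

    n = y.size
    ranks = rankdata(y, method="average")
    return norm.ppf((ranks - 0.375) / (n + 0.25))


def phenotype_residuals(
    cohort: CohortTable,
    covariates: np.ndarray | None = None,
    transform: str = "inverse_normal_rank",
) -> np.ndarray:
    """Covariate-adjusted, unit-variance phenotype residuals.

    The CPD category score is first transformed (default: rank-based
    inverse normal, chosen because the ordinal phenotype follows no
    standard distribution), then regressed on an intercept plus the
    covariate columns; the least-squares residuals are standardized to
    unit variance.
    """
    y = cohort.cpd.astype(float)
    n = y.size
    if transform == "inverse_normal_rank":
        y_star = _inverse_normal_rank(y)
    elif transform == "standardize":
        sd = y.std(ddof=0)
        if sd < 1e-12:
            raise ValidationError("constant phenotype")
        y_star = (y - y.mean()) / sd
    elif transform == "identity":
        y_star = y.copy()
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    if y_star.std(ddof=0) < 1e-12:
        raise ValidationError("constant phenotype after transform")

    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            raise ValidationError("covariate rows do not match cohort size")
        X = np.column_stack([np.ones(n), covariates])
    if n <= X.shape[1] + 2:
        raise ValidationError("too few samples for the covariate design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(X, y_star, rcond=None)
    r = y_star - X @ beta
    sd = r.std(ddof=0)
    if sd < 1e-8:
        warnings.warn("phenotype residuals are degenerate (covariates explain the phenotype)")
        if sd == 0:
            return r
    return r / sd


def phenotype_similarity(
    cohort: CohortTable,
    covariates: np.ndarray | None = None,
    transform: str = "inverse_normal_rank",
) -> SimilarityMatrix:
    """Phenotypic similarity ``S_ij = r_i r_j`` (residual cross-product).

    The residual vector is stored in ``meta['residuals']`` so the
    quadratic-form p-value machinery can reuse it.
    """
    r = phenotype_residuals(cohort, covariates=covariates, transform=transform)
    return SimilarityMatrix(
        values=np.outer(r, r),
        kind="phenotypic",
        meta={"residuals": r, "transform": transform},
    )


def combine_weights(k: SimilarityMatrix, f: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise HWU weight ``w_ij = k_ij * f_ij`` (Schur product)."""
    if k.n != f.n:
        raise ValidationError(f"dimension mismatch: k is {k.n}, f is {f.n}")
    return SimilarityMatrix(
        values=k.values * f.values,
        kind="weight",
        meta={"background": k.meta, "genetic": f.meta},
    )
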