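"""Core in-memory containers for the association pipeline.

The pipeline moves genotype dosages, per-sample phenotypes/covariates,
gene annotation and pairwise similarity matrices between stages. These
containers are deliberately thin: dosages are a plain numpy array with a
parallel boolean missingness mask, the cohort is a validated pandas
DataFrame, and similarity matrices carry their construction metadata.

Conventions
-----------
* Dosage counts the *minor* allele (0, 1, 2, or fractional after
  mean imputation); readers recode at load time.
* Genomic coordinates are 1-based inclusive (GRCh37/VCF style); BED
  input is converted at the boundary.
* Gender is coded 0 = male, 1 = female; the CPD phenotype is the
  ordinal category score in {0, 1, 2, 3} (very low ... very high).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "CohortTable",
    "GeneAnnotation",
    "SimilarityMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a container or operation contract."""


@dataclass(frozen=True)
class VariantRecord:
    """A single bi-allelic variant.

    ``maf`` is the frequency of the counted (minor) allele, computed from
    the observed calls at load time; it lives in [0, 0.5].
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str = "N"
    alt_allele: str = "N"
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if np.isfinite(self.maf) and not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValidationError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """N x M minor-allele dosage matrix with variant metadata.

    ``dosage`` holds values in {0, 1, 2} for hard calls or fractional
    values after imputation; entries where ``missing_mask`` is True are
    undefined (stored as NaN by the readers).
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValidationError(f"{len(self.samples)} samples but dosage has {n} rows")
        if len(self.variants) != m:
            raise ValidationError(f"{len(self.variants)} variants but dosage has {m} columns")
        if self.missing_mask.shape != (n, m):
            raise ValidationError("missing_mask shape differs from dosage shape")
        if len(set(self.samples)) != n:
            raise ValidationError("duplicate sample IDs")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != m:
            raise ValidationError("duplicate variant IDs")
        if not np.all(np.isfinite(self.dosage[~self.missing_mask])):
            raise ValidationError("non-finite dosage at an observed (unmasked) cell")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, snp_id: str) -> int:
        try:
            return self.variant_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown variant id {snp_id!r}") from None

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            variants=list(self.variants),
            dosage=self.dosage[keep],
            missing_mask=self.missing_mask[keep],
        )

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in keep],
            dosage=self.dosage[:, keep],
            missing_mask=self.missing_mask[:, keep],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=list(self.variants),
            dosage=self.dosage.copy(),
            missing_mask=self.missing_mask.copy(),
        )

    def observed_maf(self) -> np.ndarray:
        """Per-variant counted-allele frequency from observed calls."""
        d = np.where(self.missing_mask, np.nan, self.dosage)
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def with_recomputed_maf(self) -> "GenotypeMatrix":
        mafs = self.observed_maf()
        variants = [replace(v, maf=float(p)) for v, p in zip(self.variants, mafs)]
        return GenotypeMatrix(list(self.samples), variants, self.dosage, self.missing_mask)


REQUIRED_COHORT_COLUMNS = ("sample_id", "cpd", "gender", "race", "site", "age")


@dataclass
class CohortTable:
    """Per-sample phenotype and covariates.

    Columns: ``sample_id``, ``cpd`` (ordinal 0-3), ``gender`` (0 = male,
    1 = female), ``race`` and ``site`` (categorical), ``age`` (years).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing required columns: {missing}")
        if len(df) == 0:
            raise ValidationError("cohort table is empty")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in cohort table")
        cpd = df["cpd"].to_numpy()
        if not np.isin(cpd, [0, 1, 2, 3]).all():
            bad = sorted(set(cpd) - {0, 1, 2, 3})
            raise ValidationError(f"cpd values outside {{0,1,2,3}}: {bad}")
        gender = df["gender"].to_numpy()
        if not np.isin(gender, [0, 1]).all():
            raise ValidationError("gender codes must be 0 (male) or 1 (female)")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].astype(str).tolist()

    @property
    def cpd(self) -> np.ndarray:
        return self.table["cpd"].to_numpy(dtype=float)

    @property
    def gender(self) -> np.ndarray:
        return self.table["gender"].to_numpy(dtype=float)

    def aligned_to(self, sample_ids: Sequence[str]) -> "CohortTable":
        """Reorder/subset rows to match ``sample_ids`` exactly."""
        idx = self.table.set_index(self.table["sample_id"].astype(str)).index
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"samples absent from cohort table: {missing[:5]}")
        df = self.table.set_index(self.table["sample_id"].astype(str)).loc[list(sample_ids)]
        return CohortTable(df.reset_index(drop=True))


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene region; ``start``/``end`` are 1-based inclusive bp."""

    gene: str
    chrom: str
    start: int
    end: int
    flank_bp: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene}: start {self.start} > end {self.end}")
        if self.flank_bp < 0:
            raise ValidationError(f"gene {self.gene}: negative flank_bp")


@dataclass
class SimilarityMatrix:
    """An N x N symmetric similarity matrix.

    ``kind`` records the role in the HWU construction: ``genetic``
    (cross-product kernel f), ``background`` (heterogeneity weight k),
    ``phenotypic`` (residual cross-product S) or ``weight`` (k * f).
    """

    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValidationError("similarity matrix is not symmetric to 1e-12")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]
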