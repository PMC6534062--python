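"""Readers and writers for the formats the pipeline touches.

Supported genotype inputs:

* VCF v4.x (GT field only) via :mod:`cyvcf2`; multi-allelic sites are
  skipped with a warning, ``./.`` becomes a missing entry.
* PLINK-style text (.ped/.map pair); allele code ``0`` is missing.
* ``matrix_tsv`` — the package's own plain-text dosage matrix with
  variant metadata carried in ``##variant=`` header lines, which
  round-trips a :class:`~hwukit.containers.GenotypeMatrix` exactly
  (including fractional post-imputation dosages and the missing mask).

All readers recode dosages so the *minor* allele is counted; when the
two alleles are at exactly frequency 0.5 the ALT (or second-seen)
allele stays the counted one, making the recoding idempotent.
"""

from __future__ import annotations

import logging
import os
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CohortTable,
    GeneAnnotation,
    GenotypeMatrix,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_cohort",
    "read_gene_annotation",
    "write_genotypes_tsv",
    "write_vcf",
    "write_results",
    "read_results",
]

GENDER_CODES = {"male": 0, "m": 0, "0": 0, "female": 1, "f": 1, "1": 1}


def _recode_minor(dosage: np.ndarray, mask: np.ndarray, variants: list[VariantRecord]) -> tuple[np.ndarray, list[VariantRecord]]:
    """Flip dosages so the counted allele is the minor one; set maf.

    Frequency is computed from observed calls only. At a frequency of
    exactly 0.5 the current counted allele is kept (ties keep ALT), so
    applying the recoding twice changes nothing.
    """
    from dataclasses import replace

    out = dosage.copy()
    new_variants = []
    for j, v in enumerate(variants):
        obs = ~mask[:, j]
        if obs.sum() == 0:
            freq = np.nan
        else:
            freq = float(out[obs, j].mean() / 2.0)
        ref, alt = v.ref_allele, v.alt_allele
        if np.isfinite(freq) and freq > 0.5:
            out[obs, j] = 2.0 - out[obs, j]
            freq = 1.0 - freq
            ref, alt = alt, ref
        new_variants.append(replace(v, ref_allele=ref, alt_allele=alt,
                                    maf=float(freq) if np.isfinite(freq) else float("nan")))
    out[mask] = np.nan
    return out, new_variants


def read_genotypes(path: str, format: str = "vcf", missing_sentinel: str = "NA") -> GenotypeMatrix:
    """Read genotypes from ``path`` in one of {vcf, plink_text, matrix_tsv}.

    Returns a :class:`GenotypeMatrix` with minor-allele dosages and the
    missingness mask populated from the dialect's missing code.
    """
    if not os.path.exists(path) and format != "plink_text":
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_plink_text(path)
    if format == "matrix_tsv":
        return _read_matrix_tsv(path, missing_sentinel=missing_sentinel)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample ID in VCF header")
    rows: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) != 1:
            warnings.warn(f"skipping non-biallelic site {rec.CHROM}:{rec.POS}")
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(rec.gt_types, dtype=float)
        miss = gt == 3
        gt[miss] = np.nan
        rows.append(gt)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantRecord(chrom=str(rec.CHROM), pos=int(rec.POS), id=vid,
                                      ref_allele=str(rec.REF), alt_allele=str(rec.ALT[0])))
    vcf.close()
    if not rows:
        raise ValidationError(f"no usable bi-allelic sites in {path}")
    dosage = np.column_stack(rows)
    mask = np.isnan(dosage)
    dosage, variants = _recode_minor(dosage, mask, variants)
    return GenotypeMatrix(samples, variants, np.nan_to_num(dosage), mask)


def _read_plink_text(path: str) -> GenotypeMatrix:
    """Read a .ped/.map pair; ``path`` may be the prefix or the .ped file."""
    prefix = path[:-4] if path.endswith((".ped", ".map")) else path
    ped_path, map_path = prefix + ".ped", prefix + ".map"
    for p in (ped_path, map_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    variants: list[VariantRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValidationError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, vid, _cm, pos = parts[:4]
            variants.append(VariantRecord(chrom=chrom, pos=int(pos), id=vid))
    m = len(variants)
    samples: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValidationError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}")
            samples.append(parts[1])
            alleles = parts[6:]
            allele_rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)])
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample ID in .ped")
    n = len(samples)
    dosage = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    from dataclasses import replace

    recoded = []
    for j in range(m):
        # determine allele coding per marker; '0' is missing
        counts: dict[str, int] = {}
        order: list[str] = []
        for i in range(n):
            for a in allele_rows[i][j]:
                if a == "0":
                    continue
                if a not in counts:
                    counts[a] = 0
                    order.append(a)
                counts[a] += 1
        if len(counts) > 2:
            raise ValidationError(f"marker {variants[j].id}: more than two alleles observed")
        if not counts:
            mask[:, j] = True
            recoded.append(variants[j])
            continue
        # counted allele = minor; ties keep the second-seen allele
        if len(order) == 1:
            # monomorphic: zero copies of any minor allele at every call
            counted, other = "?", order[0]
        else:
            a0, a1 = order
            counted, other = (a1, a0) if counts[a1] <= counts[a0] else (a0, a1)
        for i in range(n):
            a, b = allele_rows[i][j]
            if a == "0" or b == "0":
                mask[i, j] = True
            else:
                dosage[i, j] = (a == counted) + (b == counted)
        obs = ~mask[:, j]
        maf = float(dosage[obs, j].mean() / 2.0) if obs.any() else float("nan")
        recoded.append(replace(variants[j], ref_allele=other, alt_allele=counted, maf=maf))
    dosage[mask] = 0.0
    return GenotypeMatrix(samples, recoded, dosage, mask)


def _read_matrix_tsv(path: str, missing_sentinel: str = "NA") -> GenotypeMatrix:
    variants: list[VariantRecord] = []
    header: list[str] | None = None
    data_rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##variant="):
                fields = line[len("##variant="):].split(";")
                if len(fields) != 6:
                    raise ValidationError(f"{path}:{lineno}: malformed ##variant header")
                vid, chrom, pos, ref, alt, maf = fields
                variants.append(VariantRecord(chrom=chrom, pos=int(pos), id=vid,
                                              ref_allele=ref, alt_allele=alt,
                                              maf=float(maf)))
                continue
            parts = line.split("\t")
            if header is None:
                if parts[0] != "sample_id":
                    raise ValidationError(f"{path}:{lineno}: first column must be sample_id")
                header = parts[1:]
                continue
            data_rows.append(parts)
    if header is None or not data_rows:
        raise ValidationError(f"{path}: no data rows")
    if variants and [v.id for v in variants] != header:
        raise ValidationError(f"{path}: ##variant headers do not match column order")
    if not variants:
        variants = [VariantRecord(chrom="?", pos=j + 1, id=vid) for j, vid in enumerate(header)]
    samples = [r[0] for r in data_rows]
    m = len(header)
    dosage = np.zeros((len(samples), m))
    mask = np.zeros((len(samples), m), dtype=bool)
    for i, row in enumerate(data_rows):
        if len(row) != m + 1:
            raise ValidationError(f"{path}: row {i + 2} has {len(row) - 1} genotype fields, expected {m}")
        for j, cell in enumerate(row[1:]):
            if cell == missing_sentinel:
                mask[i, j] = True
            else:
                dosage[i, j] = float(cell)
    need_recode = any(not np.isfinite(v.maf) for v in variants)
    if need_recode:
        d = dosage.copy()
        d[mask] = np.nan
        dosage, variants = _recode_minor(d, mask, variants)
        dosage = np.nan_to_num(dosage)
    return GenotypeMatrix(samples, variants, dosage, mask)


def write_genotypes_tsv(G: GenotypeMatrix, path: str, missing_sentinel: str = "NA") -> None:
    """Write the internal matrix_tsv dialect (exact round-trip)."""
    with open(path, "w") as fh:
        for v in G.variants:
            fh.write(f"##variant={v.id};{v.chrom};{v.pos};{v.ref_allele};{v.alt_allele};{v.maf!r}\n")
        fh.write("sample_id\t" + "\t".join(G.variant_ids) + "\n")
        for i, s in enumerate(G.samples):
            cells = [missing_sentinel if G.missing_mask[i, j] else repr(float(G.dosage[i, j]))
                     for j in range(G.n_variants)]
            fh.write(s + "\t" + "\t".join(cells) + "\n")


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write hard-call genotypes as a minimal VCF v4.2 (GT only).

    Dosages must be integral at observed cells; the counted (minor)
    allele is written as ALT so a round-trip read preserves dosages.
    """
    obs = ~G.missing_mask
    if not np.allclose(G.dosage[obs], np.round(G.dosage[obs])):
        raise ValidationError("write_vcf requires integral (hard-call) dosages")
    order = np.lexsort(([v.pos for v in G.variants], [v.chrom for v in G.variants]))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({v.chrom for v in G.variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        for j in order:
            v = G.variants[j]
            ref = v.ref_allele if v.ref_allele not in ("N", "?") else "A"
            alt = v.alt_allele if v.alt_allele not in ("N", "?") else "C"
            cells = []
            for i in range(G.n_samples):
                if G.missing_mask[i, j]:
                    cells.append("./.")
                else:
                    cells.append(gt_map[int(round(G.dosage[i, j]))])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                     + "\t".join(cells) + "\n")


def read_cohort(path: str) -> CohortTable:
    """Read the phenotype/covariate TSV.

    Required columns: sample_id, cpd, gender, race, site, age. Gender
    accepts 0/1 or male/female (case-insensitive). Rows with cpd
    outside {0,1,2,3} raise a validation error.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty cohort file") from None
    from .containers import REQUIRED_COHORT_COLUMNS

    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    gender = df["gender"].astype(str).str.strip().str.lower().map(GENDER_CODES)
    if gender.isna().any():
        bad = df.loc[gender.isna(), "gender"].unique()[:5]
        raise ValidationError(f"{path}: unrecognized gender codes {list(bad)}")
    df = df.assign(gender=gender.astype(int))
    cpd = pd.to_numeric(df["cpd"], errors="coerce")
    if cpd.isna().any() or not cpd.isin([0, 1, 2, 3]).all():
        raise ValidationError(f"{path}: cpd values must be in {{0,1,2,3}}")
    df = df.assign(cpd=cpd.astype(int))
    return CohortTable(df)


def read_gene_annotation(path: str, flank_bp: int = 0) -> list[GeneAnnotation]:
    """Read gene regions from a 4-column TSV or a BED file.

    TSV columns: gene, chrom, start, end with 1-based inclusive
    coordinates (header optional). A ``.bed`` path is interpreted as
    0-based half-open (chrom, start, end, name) and converted.
    """
    is_bed = path.endswith(".bed")
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns")
            if is_bed:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                genes.append(GeneAnnotation(gene=name, chrom=chrom, start=start + 1,
                                            end=end, flank_bp=flank_bp))
            else:
                name, chrom = parts[0], parts[1]
                if lineno == 1 and name.lower() == "gene":
                    continue
                genes.append(GeneAnnotation(gene=name, chrom=chrom, start=int(parts[2]),
                                            end=int(parts[3]), flank_bp=flank_bp))
    if not genes:
        raise ValidationError(f"{path}: no gene records")
    return genes


RESULT_COLUMNS = ("unit", "chrom", "n_snps", "U", "p_het", "p_nohet")


def write_results(results: Sequence, path: str) -> None:
    """Write gene/cluster scan results as a TSV.

    ``results`` is a sequence of (heterogeneity, homogeneous) result
    pairs as returned by the scan functions. Rows are sorted ascending
    by the heterogeneity p-value; U is the heterogeneity statistic.
    """
    if len(results) == 0:
        raise ValidationError("write_results: empty result list")
    rows = []
    for pair in results:
        het, nohet = pair
        if not getattr(het, "heterogeneity", True) and getattr(nohet, "heterogeneity", False):
            het, nohet = nohet, het
        rows.append({
            "unit": het.unit,
            "chrom": getattr(het, "chrom", "?") or "?",
            "n_snps": het.m,
            "U": f"{het.U:.6g}",
            "p_het": f"{het.p_value:.6g}",
            "p_nohet": f"{nohet.p_value:.6g}",
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df = df.sort_values("p_het", key=lambda s: s.astype(float), kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
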