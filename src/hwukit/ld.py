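"""Pairwise linkage disequilibrium from unphased dosages.

r-squared is the squared Pearson correlation of dosage vectors
(composite LD — no phasing needed); D' uses two-locus haplotype
frequencies estimated by EM from the 3x3 genotype table. "Complete LD"
groups are connected components of the graph whose edges join SNP
pairs with r2 at or above a near-1 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ValidationError

__all__ = ["LDMatrix", "ld_r2", "ld_d_prime", "compute_ld_matrix", "complete_ld_groups"]


@dataclass
class LDMatrix:
    """Pairwise r2 and D' for a set of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray
    d_prime: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.snp_ids)
        for name, m in (("r2", self.r2), ("d_prime", self.d_prime)):
            if m.shape != (k, k):
                raise ValidationError(f"{name} matrix shape {m.shape} != ({k}, {k})")
            if not np.allclose(m, m.T, atol=1e-9):
                raise ValidationError(f"{name} matrix not symmetric")
            if np.nanmin(m) < -1e-9 or np.nanmax(m) > 1 + 1e-9:
                raise ValidationError(f"{name} values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (snp_a, snp_b, r2, d_prime), upper triangle."""
        rows = []
        k = len(self.snp_ids)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append((self.snp_ids[i], self.snp_ids[j],
                             self.r2[i, j], self.d_prime[i, j]))
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "d_prime"])


def _dosage_pair(G: GenotypeMatrix, snp_a: str, snp_b: str) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = G.variant_index(snp_a), G.variant_index(snp_b)
    obs = ~(G.missing_mask[:, ia] | G.missing_mask[:, ib])
    return G.dosage[obs, ia], G.dosage[obs, ib]


def ld_r2(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite r2: squared Pearson correlation of the dosage vectors."""
    a, b = _dosage_pair(G, snp_a, snp_b)
    if a.std(ddof=0) < 1e-12 or b.std(ddof=0) < 1e-12:
        raise ValidationError(f"LD undefined for monomorphic SNP ({snp_a}, {snp_b})")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(1.0, r * r))


def _em_haplotype_freqs(a: np.ndarray, b: np.ndarray, max_iter: int = 1000,
                        tol: float = 1e-10) -> np.ndarray:
    """EM estimates of the four haplotype frequencies (AB, Ab, aB, ab)
    from unphased hard-call dosages; phase is ambiguous only in double
    heterozygotes. Returns [p11, p10, p01, p00] for counted alleles."""
    ga = np.round(a).astype(int)
    gb = np.round(b).astype(int)
    n = ga.size
    counts = np.zeros((3, 3))
    for x, y in zip(ga, gb):
        counts[x, y] += 1
    pa = ga.mean() / 2.0
    pb = gb.mean() / 2.0
    # start from linkage equilibrium
    h = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    h = np.clip(h, 1e-12, None)
    h /= h.sum()
    n_dh = counts[1, 1]  # double heterozygotes
    for _ in range(max_iter):
        # P(phase AB/ab) vs (Ab/aB) among double hets
        num = h[0] * h[3]
        den = h[0] * h[3] + h[1] * h[2]
        frac = num / den if den > 0 else 0.5
        c11 = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + n_dh * frac
        c10 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + n_dh * (1 - frac)
        c01 = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1] + n_dh * (1 - frac)
        c00 = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1] + n_dh * frac
        new = np.array([c11, c10, c01, c00]) / (2.0 * n)
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    else:
        raise ValidationError("haplotype EM did not converge in 1000 iterations")
    return h


def ld_d_prime(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Lewontin's D' from EM haplotype frequencies: |D| / D_max."""
    a, b = _dosage_pair(G, snp_a, snp_b)
    if a.std(ddof=0) < 1e-12 or b.std(ddof=0) < 1e-12:
        raise ValidationError(f"LD undefined for monomorphic SNP ({snp_a}, {snp_b})")
    h = _em_haplotype_freqs(a, b)
    pa = h[0] + h[1]
    pb = h[0] + h[2]
    d = h[0] - pa * pb
    if d >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    if d_max <= 0:
        return 0.0
    return float(min(1.0, abs(d) / d_max))


def compute_ld_matrix(G: GenotypeMatrix, snp_ids: list[str] | None = None) -> LDMatrix:
    """All-pairs r2 and D' for the given SNPs (default: all)."""
    snp_ids = snp_ids if snp_ids is not None else G.variant_ids
    k = len(snp_ids)
    r2 = np.eye(k)
    dp = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r2[i, j] = r2[j, i] = ld_r2(G, snp_ids[i], snp_ids[j])
            dp[i, j] = dp[j, i] = ld_d_prime(G, snp_ids[i], snp_ids[j])
    return LDMatrix(snp_ids=list(snp_ids), r2=r2, d_prime=dp)


def complete_ld_groups(ld: LDMatrix, threshold: float = 0.999) -> list[list[str]]:
    """Connected components of the r2 >= threshold graph (singletons
    omitted), i.e. groups of markers carrying one association signal."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix(ld.r2 >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    groups = []
    for c in range(n_comp):
        members = [ld.snp_ids[i] for i in np.nonzero(labels == c)[0]]
        if len(members) > 1:
            groups.append(members)
    return groups
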