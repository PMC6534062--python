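"""Gene-based HWU scan with and without the gender heterogeneity weight.

GENE01 carries a male-only effect (0.4 SD of liability per allele in
males, nothing in females); GENE02 and GENE03 are null. The scan tests
every gene twice on one shared covariate residualization: once with
the gender background kernel k_ij = 1 - |x_i - x_j| (cross-gender
pairs drop out) and once with k = 1 (the ordinary homogeneous test).
"""

from hwukit import (
    AnalysisConfig,
    SimulationConfig,
    adjust_pvalues,
    assign_snps_to_genes,
    run_gene_scan,
    simulate_cohort,
)

config = SimulationConfig(
    n_samples=1500,
    n_genes=3,
    snps_per_gene=10,
    causal={"GENE01": (0.4, 0.0)},
)
sim = simulate_cohort(config, seed=3)

genesets = assign_snps_to_genes(sim.genotype.variants, sim.annotation, flank_bp=1000)
pairs = run_gene_scan(sim.genotype, sim.cohort, genesets,
                      AnalysisConfig(n_components=0))

print(f"{'gene':8s} {'#SNPs':>5s} {'p_het':>10s} {'p_nohet':>10s}")
for het, nohet in pairs:
    print(f"{het.unit:8s} {het.m:5d} {het.p_value:10.3g} {nohet.p_value:10.3g}")

p_het = [het.p_value for het, _ in pairs]
print("\nBonferroni-adjusted heterogeneity p-values:",
      [f"{p:.3g}" for p in adjust_pvalues(p_het, "bonferroni")])
print("\nGENE01 should show a far smaller p-value with the gender weight "
      "than without it — the signature of a gender-heterogeneous effect, "
      "which a homogeneous test averages away. The null genes should be "
      "non-significant in both columns.")
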