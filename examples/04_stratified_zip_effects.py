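"""Stratified zero-inflated Poisson effect estimates for one SNP.

The HWU test reports significance but no effect size, so the per-SNP
effect is quantified by a ZIP regression of the ordinal CPD score on
dosage, fitted separately in males and females. Under a male-only
simulated effect the male dosage coefficient should be clearly
non-zero and the female one near zero — the same contrast the
stratified analysis of real data shows (e.g. -0.18 in males with
p ~ 1e-13 vs ~0 in females).
"""

from hwukit import SimulationConfig, simulate_cohort, stratified_snp_effects

config = SimulationConfig(
    n_samples=2717,
    n_genes=2,
    snps_per_gene=8,
    causal={"GENE01": (-0.5, 0.0)},
)
sim = simulate_cohort(config, seed=9)
causal_snp = sim.truth["causal_snps"]["GENE01"][0]

fits = stratified_snp_effects(sim.genotype, sim.cohort, causal_snp)
print(f"ZIP count-model dosage coefficient for {causal_snp}:")
for fit in fits:
    print(f"  {fit.stratum:7s} n = {fit.n:4d}  beta = {fit.beta[1]:+.3f} "
          f"(SE {fit.se_beta[1]:.3f})  Wald p = {fit.wald_p_beta[1]:.3g}  "
          f"converged = {fit.converged}")
print("\nThe male coefficient is negative and significant, the female one "
      "indistinguishable from zero: the effect-size view of the same "
      "gender heterogeneity the weighted U test detects.")
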