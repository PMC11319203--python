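"""Associate MDS methylation with haplotype-specific expression.

The outcome is the 5-mCpG rate of an MDS on one haplotype of one
individual; the predictor is the fraction of a nearby isoform's mRNA
fragments that originate from that same haplotype. Variance decompositions
then ask how much of the methylation-expression correlation survives
correction for the shared genotype.
"""

import numpy as np

import haplomethyl as hm

config = hm.SimulationConfig(
    n_individuals=60, chromosomes=(("chr1", 2_000_000),), n_regions=10, seed=29,
    expression_models=(2,), cell_flip_fraction=0.0,
)
cohort = hm.simulate_cohort(config)
result = hm.run_cohort_pipeline(cohort, min_obs=80, seed=29)

escan = result.expression_scan
n_sig = int(escan.associations["significant"].sum())
print(f"expression scan: {escan.n_tests} MDS-isoform pairs, {n_sig} significant "
      f"at Bonferroni alpha {escan.alpha:.2e}")

# variance decomposition on the strongest pipeline triple
triple = result.triples[0].standardized()
dec = hm.variance_decomposition(triple.G, triple.M, triple.E)
print(f"r2(E,G) = {dec.r2_e_g:.3f}   r2(E,M) = {dec.r2_e_m:.3f}")
print(f"r2(E,M|G) = {dec.r2_e_m_given_g:.3f}  <- what methylation explains "
      "once the ASM-QTL is removed")

mds_var = result.mds_rates.groupby("mds_id")["rate"].var()
flags = result.mds_positions.assign(
    rate_variance=result.mds_positions["mds_id"].map(mds_var),
    has_asmqtl=result.mds_positions["mds_id"].isin(result.scan.primaries["target_id"]),
    has_expression_link=result.mds_positions["mds_id"].isin(
        escan.associations.loc[escan.associations["significant"], "mds_id"]
    ),
).dropna(subset=["rate_variance"])
report, chi2, p = hm.binned_proportion_report(flags, n_bins=3)
print(f"ASM-QTL proportion, expression-linked vs not: chi2 = {chi2:.1f}, p = {p:.2g}")
print("-> expression-linked MDSs are (almost) always genetically driven")
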