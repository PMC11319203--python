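"""Map cis allele-specific methylation QTLs and apply the phase-2 filter.

Regresses inverse-normal-transformed haplotype 5-mCpG rates of each MDS on
every variant within 100 kb, Bonferroni-corrects over tests performed, and
refits the primaries with cell-composition covariates on the measured
subset (Benjamini-Hochberg FDR 0.5%).
"""

import haplomethyl as hm

config = hm.SimulationConfig(
    n_individuals=50, chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000)),
    n_regions=24, seed=2, cell_flip_fraction=0.0,
)
cohort = hm.simulate_cohort(config)
result = hm.run_cohort_pipeline(cohort, with_expression=False, min_obs=80, seed=2)

scan = result.scan
print(f"cis scan: {scan.n_tests} tests, Bonferroni alpha {scan.alpha:.2e}")
print(f"primaries: {len(scan.primaries)} MDSs with a significant ASM-QTL")

planted = {v for _, v, _ in cohort.truth.planted_asmqtl}
hit = planted & set(scan.primaries["variant_id"])
print(f"planted causal variants recovered as primary: {len(hit)}/{len(planted)}")

refit = hm.phase2_filter(
    scan.primaries, result.mds_rates.rename(columns={"mds_id": "target_id"}),
    cohort.genotypes, result.covariates, cohort.cell_fractions.to_frame(),
)
print(f"phase 2 (cell counts, FDR 0.5%): {int(refit['phase2_pass'].sum())}"
      f"/{len(refit)} primaries retained")
print("-> true cis effects survive conditioning on cell composition;"
      " confounded ones would not")
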