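# Methods

## Setting

The package analyzes haplotype-resolved methylomes: per-read calls of CpG
methylation, each phased to the paternal (P) or maternal (M) chromosome of
its individual. All internal coordinates are 0-based half-open; haplotype
order is paternal first and always carried as an explicit column. The
observation unit throughout the association machinery is the *haplotype*
(two rows per individual), with parental origin as a covariate; no
within-individual correlation correction is applied, an assumption we
document rather than hide — kinship/mixed-model corrections are out of
scope.

## Per-read calls and unit QC

A call's log-likelihood ratio supports methylation above +1.921 and
unmethylation below −1.921; the band between is ambiguous and excluded
from both numerator and denominator of every rate. CpG sites within 10 bp
are chained greedily into units. The per-unit, per-haplotype 5-mCpG rate
is methylated reliable reads over all reliable reads; missing when no
reliable read exists.

Unit filters (all boundary-inclusive on the removal side): strand bias
≥ 0.20, FRR ≤ 0.5, distance ≤ 5 bp to a SNP with MAF > 0.001, coverage
≥ 1.5× or ≤ 0.5× the cohort mean (computed once, before filtering),
dark-region overlap, phased fraction < 0.3. "Within 5 bp" is read as
distance ≤ 5 — the one genuinely ambiguous printed phrase; we chose the
inclusive side and note it here. FRR is computed per unit over all its
calls. Strand is an optional input column; without it the strand filter
is skipped and logged, since the synthetic data do not model strands.

Methylation classes: [0, 0.15) unmethylated, [0.15, 0.5) low-methylated,
[0.5, 1] methylated.

## MDS detection and cataloging

Runs are scanned per (sample, haplotype, chromosome) over units with ≥ 10
reliable reads. A measured unit at or above the class threshold breaks a
run even when the next depleted unit is within 500 bp; units below the
depth floor are removed *before* scanning and are invisible to the gap
rule. Low-methylated runs use ≥ 3 units as well (the stricter "more than
three" variant reading is treated as inconsistent with the ≥ 3 definition
used elsewhere) and are emitted only where no unmethylated run of the same
haplotype overlaps.

Cataloging: cluster runs transitively by shared units (union–find); within
a cluster drop runs whose immediately flanking units exist but have ≤ 10
reliable reads on that haplotype (a flank absent because the run touches
the edge of the measured genome passes vacuously); catalog the most
frequent run by *exact unit-set identity* — frequency by bp-overlap would
conflate distinct elements — breaking ties by bp length, then leftmost
start (a determinism tie-break we added); remove overlapping runs; repeat.
Low-methylated runs are cataloged in a second pass restricted to
coordinates free of unmethylated MDSs. The greedy caller is
cross-checked against an independently coded brute-force implementation
(networkx connected components + literal repeated max-search) on hundreds
of random instances.

The MDS rate for any (sample, haplotype) pools reliable read-level calls
across the MDS's units — read-level pooling preserves depth information
where a binarized unit-level count would not; this is a documented choice
between two defensible readings. Rates are measured cohort-wide even
though discovery can be restricted to a high-coverage subset.

## Association engine

Rates are inverse-normal transformed per target (rank-based,
Φ⁻¹((r − 0.5)/n), average ranks for ties, missing values keep their
missingness), making betas invariant to monotone transforms of the raw
rates. Each variant within 100 kb of the target's edges is tested by
least squares with covariates; the implementation residualizes outcome
and genotypes against the covariates once per target
(Frisch–Waugh–Lovell), which is algebraically exact and matches a full
multivariate OLS fit to 1e−8 (tested). Bonferroni uses the number of
tests actually performed in the run. The per-target primary is the most
significant passing variant; exact-P ties break by distance to the target
midpoint, then variant id. The secondary scan restricts to carriers of
the primary's major allele (allele 0 on an exact 50/50 split). Targets
with fewer than 100 informative haplotypes are skipped and logged.

Phase 2 refits each passing association on the subset of samples with
measured cell composition, appending cell-count columns to the
covariates, and applies Benjamini–Hochberg at q = 0.005 (the named FDR
method is our choice; only the rate is specified by the procedure being
modeled).

Cross-cohort validation uses t = (β̂_ox − β̂_nano)/√(s²_ox + s²_nano)
with n_ox − 1 degrees of freedom; the consistency summary is the fraction
of pairs with p > 0.05.

## Covariates

Leave-one-chromosome-out PCs: for each focal chromosome, the unit-rate
matrix restricted to all *other* chromosomes (optionally subsampled) is
mean-imputed per unit, column-centered and decomposed by SVD; the first
five score vectors (zero-mean) become covariates for targets on the focal
chromosome, so cis structure cannot leak into its own correction.
Missing-rate mean-imputation is our choice; the alternative (complete-case
SVD) discards too much at nanopore depths.

Add-one selection ranks candidate technical covariates by median
univariate association P over a training subset of units, then accepts
candidates in rank order while the nested-model F test improves the fit at
α = 0.05 for more than half of the test units (the stopping rule's
"most sites"), making the accepted set a prefix of the ranking.

## Expression linkage and variance decomposition

The scan's outcome is an MDS haplotype rate; the predictor is the fraction
of a nearby isoform's fragments (TSS within 100 kb of the MDS edges —
edges, not midpoint, for consistency with the cis scan) originating from
that haplotype. Rates based on fewer than 6 pooled calls and pairs with
≤ 100 informative observations are skipped. The predictor is the
fraction, unweighted by total fragment count (a weight column is
available).

Conditional r² values are computed by residualizing the predictor on the
conditioning variable; a predictor with no residual variance contributes 0
with a warning. The binned report thins to one MDS per 100 kb, bins by
rate-variance quantiles of near-equal size, reports Wilson 95% CIs per
bin, and compares ASM-QTL proportions between expression-linked and
unlinked MDSs with a 1-df chi-square without continuity correction.

## Causality

Instruments are standardized to mean-0, variance-1 allele dosages. The
Steiger direction per instrument is M→E iff |ρ_GM| > |ρ_GE| (absolute
values, so sign conventions cannot flip a verdict); the aggregate is a
two-sided exact binomial sign test against 0.5. The sensitivity statistic
r is the median of |ρ_GM|/|ρ_GE| — the inflation of expression noise at
which exactly half the instruments would flip; with an even instrument
count "half the time" resolves to the sample median. The external
reliability R statistic of the original Steiger method is intentionally
not implemented; the sign test plus r reproduce how the approach is
actually used here.

Identity test: with G standardized, E(β_ME) = β_GM·β_GE / Var(M) under
independent paths, so the ratio Var(M)·β̂_ME / (β̂_GM·β̂_GE) centers on 1
there and exceeds 1 under mediation or a shared upstream mechanism;
additive measurement noise on M or E does not bias it (tested). The
aggregate is the mean ratio with a percentile bootstrap CI over
associations (the CI method is our choice); associations with
|β_GM·β_GE| < 1e−12 are excluded and counted.

## Enrichment

Distance thinning takes the most significant variant, then repeatedly the
most significant remaining variant ≥ 1 Mb from all selected on the same
chromosome. LD proxies are variants with squared Pearson correlation
r² > 0.80 (strict) between haplotype allele vectors. Matched resampling
draws, per resample, one pool variant (from within 10 kb of MDS midpoints)
per observed ASM-QTL, matched on LD-proxy-count stratum (default strata
1, 2–5, 6–20, 21–100, >100 — the matching is specified only as "on the
number", the strata are ours) under the same > 1 Mb spacing; an
infeasible stratum widens to its neighbors with a warning. Background
probability p = Σz_i/(nN), fold = (x/n)/p, empirical P = j/N with an
upper binomial tail when j = 0.

The GWA enrichment likelihood is maximized per signal as
log Σ_m w_m·E_{c_m} − log Σ_k E_k·q̂_{k,f(i)} with
w_m = exp(χ²_m − max χ²) — algebraically the product-form likelihood up
to additive constants (verified against direct evaluation on toy
signals), with the max-subtraction keeping exponentials finite.
Frequency bins are equal-count over lead-variant MAFs; all of a signal's
variants inherit the lead's bin; q̂ comes from the caller-supplied
tested-variant table. E ≥ 0 via log-parameterization of non-baseline
annotations (the contract is the maximum, not the optimizer); the largest
annotation is fixed at E = 1. CIs by bootstrap over signals.

## Synthetic cohorts

The generator emulates: bimodal per-unit methylation (background units
mostly methylated, Beta(18, 2); a fifth unmethylated; regulatory-region
units governed by a latent activity), units as ≤ 10-bp site groups,
Poisson read depth per haplotype-unit (depth is not characterized beyond
genome-wide coverage in the data being emulated; Poisson is our choice),
exact ±|LLR| emissions with a configurable ambiguous fraction and miscall
rate, a configurable unphased-read fraction, planted cis effects
(β_gm shifts a region's activity logit per alt allele, producing
allele-specific methylation across the region's unit run), two-state
cell-composition mixing (per-individual Beta fraction; designated regions
flip activity in the second state), and confounded regions where the
nearby variant's dosage tracks the cell fraction while activity depends
on the cell fraction alone — so allele and methylation are exactly
independent given measured cell counts, the failure mode the phase-2
filter exists to remove.

Expression is generated under four causal models per region: (1) a shared
latent drives both M and E, (2) mediation G→M→E, (3) independent paths,
(4) reverse causation G→E→M. Haplotype fragment counts are
Binomial(total, softmax share of the two haplotypes' latent expression).
LD proxies are made by copying a haplotype column and flipping alleles
with probability (1 − √r²)/2. GWA signals draw the causal variant's
annotation ∝ E_c·q̂_cf within its frequency bin and give it the largest
χ² by an exponential margin.

What the generator does *not* emulate: realistic LD beyond single
proxies, recombination maps, strand effects, sequence-level errors,
imprinting, and richer-than-two-state cell mixtures. Passing tests
therefore demonstrate correctness of the algorithms and calibration of
the statistics under these mechanisms, not performance on real nanopore
data.

A practical note on directionality at pipeline precision: the
haplotype-expression *fraction* is a contrast of the two haplotypes, so
its correlation with a single haplotype's allele is attenuated by about
1/√2 relative to a direct expression measure. When the cis effect is
strong enough to create a detectable MDS, this asymmetric attenuation
exceeds the small structural gap that distinguishes reverse causation,
and the Steiger verdict from fraction-based pipeline data favors M→E
regardless of the planted model — the equal-measurement-error assumption
the Steiger approach itself carries. Model discrimination is therefore
validated on directly measured triples; the end-to-end pipeline check
plants mediation and verifies the full chain flags it.

## Problem sizes and numerics

Default verification sizes: 2,000 null tests at 500 haplotypes for
type-I calibration; 100 replicates for recovery and confounding rates;
500 instruments for directionality; 200 associations × 2,000 observations
for the identity null; 1,000 signals × 50 variants for enrichment
recovery; 5,000 resamples for sampling enrichment; and an end-to-end
cohort of 50 individuals over two 5-Mb chromosomes with 60 regulatory
regions. These sizes make every check reproducible on a laptop while
keeping Monte-Carlo error well inside the asserted bounds. Degenerate
inputs follow explicit contracts: all-tied rates transform to zeros with
a warning, rank-deficient covariate designs drop collinear columns,
monomorphic variants are excluded from LD, empty resample strata widen,
and empty inputs raise errors naming the offending field.
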