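"""Synthetic cohort generation with known ground truth.

Real haplotype-resolved nanopore methylome cohorts are access-restricted,
so every downstream stage of this package is exercised against simulated
cohorts in which the answers are planted and recoverable:

* CpG sites are placed along each chromosome and grouped into <=10-bp
  units; per-unit methylation probabilities are drawn from a bimodal
  mixture (mostly-methylated background, unmethylated regulatory regions),
  reproducing the bimodal per-unit rate distribution of real methylomes.
* Regulatory regions carry a latent per-haplotype activity on the logit
  scale; a planted cis variant shifts that activity by ``beta_gm`` per alt
  allele, producing allele-specific methylation across a contiguous run of
  units (a recoverable MDS plus ASM-QTL).
* Cell-type composition enters as a two-state mixture: each individual has
  a mixing fraction for a second cell state in which designated regions
  flip activity; regions can be made *confounded* (no true cis effect, but
  the cell fraction tracks a variant's dosage), the failure mode the
  phase-2 cell-count filter exists to remove.
* Haplotype-specific expression is generated under four causal models
  (shared mechanism, mediation through methylation, independent paths, and
  reverse causation), and GWA-signal tables are generated with causal
  variants enriched in chosen annotations within allele-frequency bins.

Per-read calls are emitted nanopolish-style: one row per read x unit with a
log-likelihood ratio, a haplotype label (P/M/U) and a sample id. With a
fixed seed every generator is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_fraction, sigmoid, spawn_rng
from .asmqtl import HaplotypeGenotypes
from .causality import CausalTriple
from .qc import LLR_THRESHOLD, group_cpg_sites


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults define the study conditions."""

    seed: int = 0
    n_individuals: int = 50
    chromosomes: tuple = (("chr1", 5_000_000), ("chr2", 5_000_000))
    cpg_density: float = 0.2          # background CpG sites per kb
    variant_density: float = 0.5      # variants per kb
    maf_range: tuple = (0.05, 0.5)    # uniform MAF distribution
    n_regions: int = 60               # regulatory regions per genome
    region_n_units: int = 6           # CpG units per region
    region_unit_spacing: int = 150    # bp between region units
    sites_per_region_unit: int = 3
    asm_fraction: float = 0.5         # regions with a planted cis effect
    confounded_fraction: float = 0.0  # regions confounded by cell fraction
    beta_gm: float = 3.0              # allelic shift of region-activity logit
    alpha_active: float = 2.5         # baseline activity logit of regions
    region_noise_sd: float = 0.5      # shared latent noise (eta)
    region_obs_sd: float = 0.3        # residual activity noise (epsilon)
    read_depth_mean: float = 20.0     # reads per haplotype per unit
    llr_magnitude: float = 3.0        # |LLR| of confident calls
    ambiguous_call_rate: float = 0.05
    miscall_rate: float = 0.02
    phased_rate: float = 0.8          # fraction of reads with haplotype != U
    p_active: tuple = (1.0, 19.0)     # Beta params, unit meth prob, active state
    p_inactive: tuple = (18.0, 2.0)   # Beta params, inactive state
    background_unmeth_fraction: float = 0.2
    cell_fraction_beta: tuple = (2.0, 6.0)  # per-individual second-state fraction
    cell_flip_fraction: float = 0.2   # regions that flip state in cell type 2
    expression_models: tuple = (1, 2, 3, 4)  # cycled over expressed regions
    b_t: float = 1.0
    b_m: float = 0.8
    b_e: float = 0.8
    b_g: float = 0.8
    expression_noise_sd: float = 0.5
    fragments_per_isoform: float = 80.0

    def validate(self) -> None:
        for name in ("asm_fraction", "confounded_fraction", "ambiguous_call_rate",
                     "miscall_rate", "phased_rate", "background_unmeth_fraction",
                     "cell_flip_fraction"):
            check_fraction(getattr(self, name), name)
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name, length in self.chromosomes:
            if length < 100_000:
                raise ValueError(f"chromosomes: {name} shorter than 100 kb")
        if self.cpg_density <= 0:
            raise ValueError("cpg_density must be positive")
        if self.variant_density <= 0:
            raise ValueError("variant_density must be positive")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.read_depth_mean <= 0:
            raise ValueError("read_depth_mean must be positive")
        if self.llr_magnitude <= LLR_THRESHOLD:
            raise ValueError("llr_magnitude must exceed the ambiguity threshold 1.921")
        for m in self.expression_models:
            if m not in (1, 2, 3, 4):
                raise ValueError(f"expression_models: unknown model id {m}")


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort."""

    planted_mds: list            # (region_id, chrom, start, end, class)
    planted_asmqtl: list         # (region_id, variant_id, beta_gm)
    confounded: list             # (region_id, variant_id)
    region_model: dict           # region_id -> causal model id
    region_units: dict           # region_id -> list of (start, end)
    # latent pieces per region, arrays shaped (n_individuals, 2):
    region_allele: dict
    region_t_part: dict          # beta_gm*allele + shared noise eta
    region_eps: dict             # residual activity noise
    region_variant: dict         # region_id -> cis variant id
    region_tss: dict             # region_id -> (chrom, pos)


@dataclass
class SimulatedCohort:
    calls: pd.DataFrame
    units: pd.DataFrame          # chrom, start, end, n_sites, is_region, region_id
    genotypes: HaplotypeGenotypes
    cell_fractions: pd.Series    # per sample
    truth: CohortTruth
    config: SimulationConfig

    @property
    def samples(self) -> list:
        return self.genotypes.samples


def _place_units(config: SimulationConfig, rng: np.random.Generator):
    """Background + region CpG unit layout per chromosome."""
    rows = []
    region_rows = []
    n_chrom = len(config.chromosomes)
    regions_per_chrom = [
        config.n_regions // n_chrom + (1 if i < config.n_regions % n_chrom else 0)
        for i in range(n_chrom)
    ]
    region_id = 0
    for (chrom, length), n_reg in zip(config.chromosomes, regions_per_chrom):
        region_width = (config.region_n_units - 1) * config.region_unit_spacing + 50
        # evenly spaced anchors with jitter; guaranteed non-overlapping
        slot = (length - 200_000) // max(n_reg, 1)
        anchors = [
            100_000 + i * slot + int(rng.integers(0, max(slot - region_width - 1, 1)))
            for i in range(n_reg)
        ]
        region_intervals = []
        for a in anchors:
            region_intervals.append((a, a + region_width, f"R{region_id:03d}"))
            region_id += 1
        # background sites avoiding regions
        n_bg = rng.poisson(config.cpg_density / 1000.0 * length)
        bg = np.sort(rng.choice(length, size=n_bg, replace=False))
        for lo, hi, _ in region_intervals:
            bg = bg[(bg < lo - 20) | (bg >= hi + 20)]
        for unit_sites in group_cpg_sites(bg.tolist()):
            rows.append((chrom, unit_sites[0], unit_sites[-1] + 2, len(unit_sites), False, ""))
        for lo, hi, rid in region_intervals:
            for u in range(config.region_n_units):
                start = lo + u * config.region_unit_spacing
                n_sites = config.sites_per_region_unit
                rows.append((chrom, start, start + 2 * n_sites, n_sites, True, rid))
            region_rows.append((rid, chrom, lo, hi))
    units = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "is_region", "region_id"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    regions = pd.DataFrame(region_rows, columns=["region_id", "chrom", "start", "end"])
    return units, regions


def _simulate_genotypes(config: SimulationConfig, rng: np.random.Generator):
    samples = [f"S{i:03d}" for i in range(config.n_individuals)]
    var_rows = []
    blocks = []
    vid = 0
    for chrom, length in config.chromosomes:
        n_var = rng.poisson(config.variant_density / 1000.0 * length)
        pos = np.sort(rng.choice(length, size=n_var, replace=False))
        mafs = rng.uniform(*config.maf_range, size=n_var)
        alleles = (rng.random((n_var, config.n_individuals, 2)) < mafs[:, None, None])
        for p, m in zip(pos, mafs):
            var_rows.append((f"var{vid:05d}", chrom, int(p), m))
            vid += 1
        blocks.append(alleles)
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos", "maf"])
    allele_array = np.concatenate(blocks, axis=0).astype(np.int8)
    return HaplotypeGenotypes(allele_array, variants, samples)


def make_ld_proxy(
    genotypes: HaplotypeGenotypes, variant_id: str, r2_target: float,
    rng: np.random.Generator, new_id: str, pos_offset: int = 1000,
) -> HaplotypeGenotypes:
    """Append a proxy variant in LD with an existing one.

    The proxy copies the source haplotype column and flips each haplotype
    allele independently with probability chosen so the expected r^2
    roughly matches ``r2_target`` (flip probability (1 - sqrt(r2))/2).
    """
    i = genotypes._vidx[variant_id]
    src = genotypes.alleles[i].copy()
    flip_p = (1.0 - np.sqrt(r2_target)) / 2.0
    flips = rng.random(src.shape) < flip_p
    proxy = np.where(flips, 1 - src, src).astype(np.int8)
    row = genotypes.variants.iloc[i]
    new_variants = pd.concat(
        [genotypes.variants,
         pd.DataFrame([{"variant_id": new_id, "chrom": row["chrom"],
                        "pos": row["pos"] + pos_offset, "maf": row["maf"]}])],
        ignore_index=True,
    )
    new_alleles = np.concatenate([genotypes.alleles, proxy[None]], axis=0)
    return HaplotypeGenotypes(new_alleles, new_variants, genotypes.samples)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate per-read methylation calls, genotypes and ground truth."""
    config.validate()
    rng_layout = spawn_rng(config.seed, 1)
    rng_geno = spawn_rng(config.seed, 2)
    rng_state = spawn_rng(config.seed, 3)
    rng_reads = spawn_rng(config.seed, 4)

    units, regions = _place_units(config, rng_layout)
    genotypes = _simulate_genotypes(config, rng_geno)
    samples = genotypes.samples
    n = config.n_individuals

    cell_fractions = pd.Series(
        rng_state.beta(*config.cell_fraction_beta, size=n), index=samples, name="cell_fraction"
    )

    # per-unit base methylation probabilities
    n_units = len(units)
    p_active_u = rng_state.beta(*config.p_active, size=n_units)
    p_inactive_u = rng_state.beta(*config.p_inactive, size=n_units)
    bg_unmeth = rng_state.random(n_units) < config.background_unmeth_fraction

    # region roles
    region_ids = list(regions["region_id"])
    n_reg = len(region_ids)
    n_asm = int(round(config.asm_fraction * n_reg))
    n_conf = int(round(config.confounded_fraction * n_reg))
    roles = ["asm"] * n_asm + ["confounded"] * n_conf + ["plain"] * (n_reg - n_asm - n_conf)
    rng_state.shuffle(roles)
    flip_in_cell2 = rng_state.random(n_reg) < config.cell_flip_fraction

    truth = CohortTruth([], [], [], {}, {}, {}, {}, {}, {}, {})
    theta = cell_fractions.to_numpy()

    # per-region latent activity and the planted variant
    unit_w = np.zeros((n_units, n, 2))  # depletion weight per unit x sample x hap
    # background: constant across samples
    w_bg = np.where(bg_unmeth, 1.0, 0.0)
    unit_w[:] = w_bg[:, None, None]

    model_cycle = list(config.expression_models)
    for r_i, row in enumerate(regions.itertuples(index=False)):
        rid = row.region_id
        in_region = units["region_id"] == rid
        unit_idx = np.flatnonzero(in_region)
        truth.region_units[rid] = [
            (int(s), int(e)) for s, e in zip(units.loc[in_region, "start"],
                                             units.loc[in_region, "end"])
        ]
        mid = (row.start + row.end) // 2
        near = genotypes.variants[
            (genotypes.variants["chrom"] == row.chrom)
            & ((genotypes.variants["pos"] - mid).abs() <= 100_000)
        ]
        if len(near) == 0:
            variant_id = None
        else:
            variant_id = near.iloc[int((near["pos"] - mid).abs().argmin())]["variant_id"]
        role = roles[r_i]

        g = np.zeros((n, 2))
        if variant_id is not None:
            vi = genotypes._vidx[variant_id]
            g = genotypes.alleles[vi].astype(float)  # (n, 2), paternal/maternal

        eta = rng_state.normal(0.0, config.region_noise_sd, size=(n, 2))
        eps = rng_state.normal(0.0, config.region_obs_sd, size=(n, 2))
        beta = config.beta_gm if role == "asm" and variant_id is not None else 0.0
        logit = config.alpha_active - beta * g + eta + eps
        if role == "confounded" and variant_id is not None:
            # redraw the variant so its dosage tracks the cell fraction, and
            # make region activity depend on the cell fraction alone: allele
            # and methylation are then independent given the cell fraction
            z = (theta - theta.mean()) / max(theta.std(), 1e-9)
            p_alt = np.clip(0.5 + 0.35 * np.tanh(z), 0.02, 0.98)
            vi = genotypes._vidx[variant_id]
            genotypes.alleles[vi] = (
                rng_state.random((n, 2)) < p_alt[:, None]
            ).astype(np.int8)
            g = genotypes.alleles[vi].astype(float)
            logit = config.alpha_active + eta + eps - 2.5 * z[:, None]
            truth.confounded.append((rid, variant_id))
        w = sigmoid(logit)
        if flip_in_cell2[r_i] and role != "confounded":
            w = (1 - theta[:, None]) * w + theta[:, None] * (1 - w)
        unit_w[unit_idx] = w[None, :, :]

        planted_class = "low_methylated" if (flip_in_cell2[r_i] and role != "confounded") \
            else "unmethylated"
        truth.planted_mds.append((rid, row.chrom, int(units.loc[in_region, "start"].min()),
                                  int(units.loc[in_region, "end"].max()), planted_class))
        if role == "asm" and variant_id is not None:
            truth.planted_asmqtl.append((rid, variant_id, beta))
        truth.region_model[rid] = model_cycle[r_i % len(model_cycle)]
        truth.region_allele[rid] = g
        truth.region_t_part[rid] = -beta * g + eta if role == "asm" else eta
        truth.region_eps[rid] = eps
        truth.region_variant[rid] = variant_id
        truth.region_tss[rid] = (row.chrom, int(row.end + 5_000))

    # emit per-read calls
    m_prob = unit_w * p_active_u[:, None, None] + (1 - unit_w) * p_inactive_u[:, None, None]
    depth = rng_reads.poisson(config.read_depth_mean, size=(n_units, n, 2))
    call_p = m_prob * (1 - config.miscall_rate) + (1 - m_prob) * config.miscall_rate

    total_reads = int(depth.sum())
    unit_rep = np.repeat(np.arange(n_units * n * 2), depth.ravel())
    u_idx = unit_rep // (n * 2)
    s_idx = (unit_rep // 2) % n
    h_idx = unit_rep % 2
    meth = rng_reads.random(total_reads) < call_p.ravel()[unit_rep]
    ambiguous = rng_reads.random(total_reads) < config.ambiguous_call_rate
    unphased = rng_reads.random(total_reads) >= config.phased_rate
    llr = np.where(meth, config.llr_magnitude, -config.llr_magnitude)
    llr = np.where(ambiguous,
                   rng_reads.uniform(-LLR_THRESHOLD, LLR_THRESHOLD, size=total_reads), llr)
    hap = np.where(unphased, "U", np.where(h_idx == 0, "P", "M"))

    chrom_codes = units["chrom"].astype("category")
    calls = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(
                chrom_codes.cat.codes.to_numpy()[u_idx], categories=chrom_codes.cat.categories
            ),
            "unit_start": units["start"].to_numpy()[u_idx],
            "unit_end": units["end"].to_numpy()[u_idx],
            "n_sites": units["n_sites"].to_numpy()[u_idx],
            "sample_id": pd.Categorical.from_codes(s_idx, categories=samples),
            "read_id": np.arange(total_reads, dtype=np.int64),
            "haplotype": pd.Categorical(hap, categories=["P", "M", "U"]),
            "llr": llr.astype(np.float32),
        }
    )
    return SimulatedCohort(calls, units, genotypes, cell_fractions, truth, config)


def simulate_expression(cohort: SimulatedCohort, seed: int | None = None) -> pd.DataFrame:
    """Haplotype-assigned mRNA fragment counts per region isoform.

    One isoform per regulatory region, generated under the region's causal
    model (cohort.truth.region_model):

    1. a latent T = f(G) drives both M and E (shared mechanism);
    2. E depends on M which depends on G (mediation);
    3. G affects M and E via independent noise paths;
    4. E = f(G) and M responds to E (reverse causation).

    Returns a table (sample_id, isoform_id, tss_chrom, tss_pos,
    total_fragments, paternal_fragments).
    """
    config = cohort.config
    rng = spawn_rng(config.seed if seed is None else seed, 6)
    truth = cohort.truth
    n = config.n_individuals
    rows = []
    for rid, model in truth.region_model.items():
        g = truth.region_allele[rid]          # (n, 2)
        t_part = truth.region_t_part[rid]     # systematic + shared noise
        eps = truth.region_eps[rid]
        m_lat = t_part + eps
        noise = rng.normal(0.0, config.expression_noise_sd, size=(n, 2))
        if model == 1:
            e_lat = config.b_e * t_part + noise
        elif model == 2:
            e_lat = config.b_m * m_lat + noise
        elif model == 3:
            g_c = g - g.mean()
            e_lat = config.b_e * (-config.beta_gm) * g_c + noise
        elif model == 4:
            e_lat = t_part / config.b_m
        else:
            raise ValueError(f"unknown model id {model}")
        share_p = 1.0 / (1.0 + np.exp(-(e_lat[:, 0] - e_lat[:, 1])))
        total = rng.poisson(config.fragments_per_isoform, size=n)
        paternal = rng.binomial(total, share_p)
        chrom, tss = truth.region_tss[rid]
        for i, sample in enumerate(cohort.samples):
            rows.append((sample, f"iso_{rid}", chrom, tss, int(total[i]), int(paternal[i])))
    return pd.DataFrame(
        rows,
        columns=["sample", "isoform_id", "tss_chrom", "tss_pos",
                 "total_fragments", "paternal_fragments"],
    )


@dataclass
class TripleParams:
    """Effect sizes and noise scales for the four causal models."""

    b_t: float = 1.0   # G -> latent T (model 1)
    b_m: float = 1.0   # M's upstream coefficient (models 1, 2, 4)
    b_g: float = 1.0   # G -> M (models 2, 3) or G -> E (model 4)
    b_e: float = 1.0   # T -> E (model 1) or G -> E (model 3)
    sd_t: float = 0.5
    sd_m: float = 1.0
    sd_e: float = 1.0
    meas_sd_m: float = 0.0  # added measurement noise on M
    meas_sd_e: float = 0.0  # added measurement noise on E


def simulate_causal_triples(
    model: int,
    n_instruments: int,
    n_obs: int,
    params: TripleParams = TripleParams(),
    maf: float = 0.3,
    seed: int = 0,
) -> list[CausalTriple]:
    """Direct (G, M, E) triples under one of the four causal models.

    G is a per-individual allele count ~ Binomial(2, maf), or a standard
    normal "dosage" when ``maf`` is None (unit variance exactly, handy for
    closed-form checks). Measurement noise is added after the structural
    equations, so attenuation of the G-M and G-E correlations can be
    controlled separately.
    """
    if model not in (1, 2, 3, 4):
        raise ValueError(f"unknown model id {model}")
    p = params
    rng = spawn_rng(seed, 7, model)
    triples = []
    for i in range(n_instruments):
        if maf is None:
            G = rng.normal(0.0, 1.0, size=n_obs)
        else:
            G = rng.binomial(2, maf, size=n_obs).astype(float)
        if model == 1:
            T = p.b_t * G + rng.normal(0, p.sd_t, n_obs)
            M = p.b_m * T + rng.normal(0, p.sd_m, n_obs)
            E = p.b_e * T + rng.normal(0, p.sd_e, n_obs)
        elif model == 2:
            M = p.b_g * G + rng.normal(0, p.sd_m, n_obs)
            E = p.b_m * M + rng.normal(0, p.sd_e, n_obs)
        elif model == 3:
            M = p.b_g * G + rng.normal(0, p.sd_m, n_obs)
            E = p.b_e * G + rng.normal(0, p.sd_e, n_obs)
        else:
            E = p.b_g * G + rng.normal(0, p.sd_e, n_obs)
            M = p.b_m * E + rng.normal(0, p.sd_m, n_obs)
        M = M + rng.normal(0, p.meas_sd_m, n_obs) if p.meas_sd_m > 0 else M
        E = E + rng.normal(0, p.meas_sd_e, n_obs) if p.meas_sd_e > 0 else E
        triples.append(CausalTriple(f"inst{i:04d}", G, M, E))
    return triples


def simulate_qtl_panel(
    n_individuals: int = 500,
    n_variants: int = 20,
    causal_index: int | None = None,
    beta: float = 0.0,
    maf_range: tuple = (0.1, 0.5),
    noise_sd: float = 1.0,
    window_bp: int = 100_000,
    seed: int = 0,
):
    """Light-weight single-target panel for association-engine tests.

    Generates haplotype genotypes for ``n_variants`` variants within a cis
    window, a covariate frame (age, sex, parental haplotype), and a
    haplotype-level rate table where the target value is
    ``beta * allele(causal) + 0.02 * age_z + noise``. Returns
    (target_rates, positions, genotypes, covariates).
    """
    rng = spawn_rng(seed, 8)
    samples = [f"S{i:04d}" for i in range(n_individuals)]
    mafs = rng.uniform(*maf_range, size=n_variants)
    alleles = (rng.random((n_variants, n_individuals, 2)) < mafs[:, None, None]).astype(np.int8)
    pos = np.sort(rng.choice(window_bp, size=n_variants, replace=False)) + 10_000
    variants = pd.DataFrame(
        {"variant_id": [f"v{i:04d}" for i in range(n_variants)],
         "chrom": "chr1", "pos": pos, "maf": mafs}
    )
    genotypes = HaplotypeGenotypes(alleles, variants, samples)

    age = rng.normal(50, 10, n_individuals)
    sex = rng.integers(0, 2, n_individuals)
    pheno = pd.DataFrame({"age": age, "sex": sex}, index=pd.Index(samples, name="sample"))
    from .covariates import build_covariate_frame

    covariates = build_covariate_frame(pheno)

    obs_index = covariates.index
    g = np.zeros(len(obs_index))
    if causal_index is not None:
        g = genotypes.allele_matrix([variants["variant_id"][causal_index]], obs_index)[:, 0]
    age_z = (covariates["age"] - covariates["age"].mean()) / covariates["age"].std()
    y = beta * g + 0.02 * age_z.to_numpy() + rng.normal(0, noise_sd, len(obs_index))
    target_rates = pd.DataFrame(
        {
            "target_id": "T0",
            "sample": obs_index.get_level_values("sample"),
            "haplotype": obs_index.get_level_values("haplotype"),
            "rate": y,
        }
    )
    positions = pd.DataFrame(
        [{"target_id": "T0", "chrom": "chr1", "start": 55_000, "end": 56_000}]
    )
    return target_rates, positions, genotypes, covariates


def simulate_gwa_dataset(
    q_hat: pd.DataFrame,
    true_e: dict,
    n_signals: int,
    variants_per_signal: int = 50,
    n_background: int = 20_000,
    seed: int = 0,
):
    """GWA-signal table with causal variants enriched in chosen annotations.

    ``q_hat``: annotations x frequency-bin background proportions, columns
    summing to 1; ``true_e``: annotation -> enrichment E_c >= 0. Per signal
    the causal annotation is drawn with probability proportional to
    E_c * q_hat[c, f]; the remaining variants follow q_hat[., f]. The
    causal variant receives the largest chi-square in its signal by a
    margin, so it carries almost all of the likelihood weight. Signals are
    spread over the bins in equal counts; lead MAFs are drawn uniformly
    within per-bin MAF intervals. Returns (signals, background) tables.
    """
    annotations = list(q_hat.index)
    bins = list(q_hat.columns)
    n_bins = len(bins)
    if n_signals < n_bins:
        raise ValueError("n_signals must be >= number of frequency bins")
    for f in bins:
        if abs(q_hat[f].sum() - 1.0) > 1e-8:
            raise ValueError(f"q_hat column {f} must sum to 1")
    e = np.array([true_e[a] for a in annotations], dtype=float)
    if np.any(e < 0):
        raise ValueError("enrichments must be >= 0")
    rng = spawn_rng(seed, 9)

    maf_edges = np.linspace(0.01, 0.5, n_bins + 1)
    sig_rows = []
    for i in range(n_signals):
        f_i = i % n_bins
        q_f = q_hat[bins[f_i]].to_numpy()
        p_causal = e * q_f
        p_causal = p_causal / p_causal.sum()
        causal_a = annotations[rng.choice(len(annotations), p=p_causal)]
        others = rng.choice(len(annotations), size=variants_per_signal - 1, p=q_f)
        chi2_others = rng.chisquare(1, size=variants_per_signal - 1) + 20.0
        chi2_causal = (chi2_others.max() if len(chi2_others) else 20.0) + 5.0 + rng.exponential(1.0)
        lead_maf = rng.uniform(maf_edges[f_i], maf_edges[f_i + 1])
        sig_id = f"sig{i:05d}"
        sig_rows.append((sig_id, f"{sig_id}_causal", chi2_causal, causal_a, True, lead_maf))
        for j, a_j in enumerate(others):
            sig_rows.append((sig_id, f"{sig_id}_m{j:03d}", chi2_others[j],
                             annotations[a_j], False, lead_maf))
    signals = pd.DataFrame(
        sig_rows, columns=["signal_id", "variant_id", "chi2", "annotation", "is_lead", "maf"]
    )

    bg_rows = []
    per_bin = n_background // n_bins
    for f_i, f in enumerate(bins):
        q_f = q_hat[f].to_numpy()
        ann = rng.choice(len(annotations), size=per_bin, p=q_f)
        mafs = rng.uniform(maf_edges[f_i], maf_edges[f_i + 1], size=per_bin)
        bg_rows.extend((annotations[a], m) for a, m in zip(ann, mafs))
    background = pd.DataFrame(bg_rows, columns=["annotation", "maf"])
    return signals, background
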