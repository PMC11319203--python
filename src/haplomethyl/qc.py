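"""Per-read call processing and CpG-unit quality control.

Turns per-read, per-unit methylation calls (nanopolish-style log-likelihood
ratios) into haplotype-resolved per-unit 5-mCpG rates, and applies the
unit-level QC filters: strand bias, fraction of reliable reads (FRR),
proximity to common SNPs, coverage extremes, dark-region masking and
phased-read fraction.

A call is *reliable* when |LLR| > 1.921; calls inside the ambiguous band
[-1.921, +1.921] are discarded from rate numerators and denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: LLR magnitude below which a per-read call is considered ambiguous.
LLR_THRESHOLD = 1.921

#: Methylation-class boundaries on the 5-mCpG rate scale.
UNMETHYLATED_MAX = 0.15
LOW_METHYLATED_MAX = 0.50


@dataclass(frozen=True)
class QCThresholds:
    """Unit-removal thresholds; each is boundary-inclusive on the removal side."""

    max_strand_bias: float = 0.20     # drop if strand bias >= this
    min_frr: float = 0.5              # drop if FRR <= this
    snp_distance: int = 5             # drop if <= this many bp from a common SNP
    snp_maf: float = 0.001            # SNP counts as "known" if MAF > this
    max_coverage_ratio: float = 1.5   # drop if coverage >= this x cohort mean
    min_coverage_ratio: float = 0.5   # drop if coverage <= this x cohort mean
    min_phased_fraction: float = 0.3  # drop if phased fraction < this


def group_cpg_sites(site_positions, max_gap: int = 10) -> list[list[int]]:
    """Chain sorted CpG site positions into units.

    A site joins the current unit iff its distance to the previous site is
    <= ``max_gap`` bp. The returned units partition the input.
    """
    positions = list(site_positions)
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("site positions must be sorted and unique")
    units: list[list[int]] = []
    for pos in positions:
        if units and pos - units[-1][-1] <= max_gap:
            units[-1].append(pos)
        else:
            units.append([pos])
    return units


def assign_read_phase(
    read_het_alleles,
    paternal: dict,
    maternal: dict,
    min_variants: int = 3,
    min_consistency: float = 0.70,
) -> str:
    """Assign a read to a parental haplotype from its heterozygous alleles.

    ``read_het_alleles`` is a sequence of (variant_id, allele) pairs observed
    on the read; ``paternal``/``maternal`` map variant_id -> allele on that
    parental haplotype. Returns 'P', 'M' or 'U' (unphased).

    A read is phased only if it overlaps at least ``min_variants``
    heterozygous variants and at least ``min_consistency`` of them agree
    with one parent. An allele matching neither haplotype counts as a
    mismatch to both.
    """
    n = p_match = m_match = 0
    for variant, allele in read_het_alleles:
        if variant not in paternal or variant not in maternal:
            continue
        n += 1
        if allele == paternal[variant]:
            p_match += 1
        if allele == maternal[variant]:
            m_match += 1
    if n < min_variants:
        return "U"
    if p_match / n >= min_consistency:
        return "P"
    if m_match / n >= min_consistency:
        return "M"
    return "U"


def unit_haplotype_rate(llrs, threshold: float = LLR_THRESHOLD):
    """Counts and 5-mCpG rate for one unit x sample x haplotype.

    Returns ``(rate, n_methylated, n_unmethylated, n_ambiguous)``; the rate
    is NaN when no reliable call is present.
    """
    llrs = np.asarray(list(llrs), dtype=float)
    n_meth = int(np.sum(llrs > threshold))
    n_unmeth = int(np.sum(llrs < -threshold))
    n_ambig = llrs.size - n_meth - n_unmeth
    if n_meth + n_unmeth == 0:
        return float("nan"), n_meth, n_unmeth, n_ambig
    return n_meth / (n_meth + n_unmeth), n_meth, n_unmeth, n_ambig


def classify_rate(rate: float) -> str:
    """Classify a 5-mCpG rate: unmethylated <0.15 <= low_methylated <0.5 <= methylated."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if rate < UNMETHYLATED_MAX:
        return "unmethylated"
    if rate < LOW_METHYLATED_MAX:
        return "low_methylated"
    return "methylated"


def aggregate_calls(calls: pd.DataFrame, threshold: float = LLR_THRESHOLD) -> pd.DataFrame:
    """Aggregate per-read calls into per (unit, sample, haplotype) counts.

    ``calls`` columns: chrom, unit_start, unit_end, sample_id, haplotype, llr.
    Unphased reads (haplotype == 'U') are excluded from haplotype rates but
    are reflected in ``unit_qc_stats``.

    Returns a long table with columns chrom, start, end, sample, haplotype,
    n_meth, n_unmeth, n_ambig, n_reliable, rate.
    """
    phased = calls[calls["haplotype"].isin(["P", "M"])].copy()
    phased["meth"] = (phased["llr"] > threshold).astype(np.int32)
    phased["unmeth"] = (phased["llr"] < -threshold).astype(np.int32)
    grouped = (
        phased.groupby(["chrom", "unit_start", "unit_end", "sample_id", "haplotype"],
                       observed=True, sort=True)
        .agg(n_meth=("meth", "sum"), n_unmeth=("unmeth", "sum"), n_calls=("llr", "size"))
        .reset_index()
    )
    grouped["n_ambig"] = grouped["n_calls"] - grouped["n_meth"] - grouped["n_unmeth"]
    grouped["n_reliable"] = grouped["n_meth"] + grouped["n_unmeth"]
    with np.errstate(invalid="ignore"):
        grouped["rate"] = grouped["n_meth"] / grouped["n_reliable"]
    grouped = grouped.rename(
        columns={"unit_start": "start", "unit_end": "end", "sample_id": "sample"}
    )
    return grouped.drop(columns=["n_calls"])


def unit_qc_stats(calls: pd.DataFrame, threshold: float = LLR_THRESHOLD) -> pd.DataFrame:
    """Cohort-level QC statistics per unit.

    Computes FRR (fraction of reliable reads over all calls at the unit),
    phased fraction, total coverage, and — when a ``strand`` column is
    present — strand bias as |forward rate - reverse rate| over reliable
    calls. Without strand information ``strand_bias`` is NaN and the strand
    filter is skipped downstream.
    """
    df = calls.copy()
    df["reliable"] = df["llr"].abs() > threshold
    df["phased"] = df["haplotype"].isin(["P", "M"])
    keys = ["chrom", "unit_start", "unit_end"]
    stats = (
        df.groupby(keys, observed=True, sort=True)
        .agg(n_calls=("llr", "size"), frr=("reliable", "mean"), phased_fraction=("phased", "mean"))
        .reset_index()
    )
    if "strand" in df.columns:
        rel = df[df["reliable"]].copy()
        rel["meth"] = rel["llr"] > threshold
        by_strand = (
            rel.groupby(keys + ["strand"], observed=True)["meth"].mean().unstack("strand")
        )
        fwd = by_strand.get("+")
        rev = by_strand.get("-")
        if fwd is not None and rev is not None:
            bias = (fwd - rev).abs().rename("strand_bias").reset_index()
            stats = stats.merge(bias, on=keys, how="left")
    if "strand_bias" not in stats.columns:
        stats["strand_bias"] = np.nan
    stats = stats.rename(columns={"unit_start": "start", "unit_end": "end"})
    return stats


@dataclass
class FilterResult:
    kept: pd.DataFrame
    drop_log: pd.DataFrame
    skipped_filters: list = field(default_factory=list)


def filter_units(
    stats: pd.DataFrame,
    snps: pd.DataFrame | None = None,
    dark_regions: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> FilterResult:
    """Apply the five unit-QC filters; a unit is dropped if ANY filter fires.

    ``stats`` is the output of :func:`unit_qc_stats`. ``snps`` has columns
    chrom, pos (0-based), maf; ``dark_regions`` has chrom, start, end
    (0-based half-open). The drop log records every fired reason per unit.
    """
    required = {"chrom", "start", "end", "n_calls", "frr", "phased_fraction"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"missing QC fields: {sorted(missing)}")

    th = thresholds
    reasons: dict[str, np.ndarray] = {}
    n = len(stats)
    mean_cov = stats["n_calls"].mean()
    cov_ratio = stats["n_calls"] / mean_cov if mean_cov > 0 else np.zeros(n)

    skipped = []
    if stats["strand_bias"].notna().any():
        reasons["strand_bias"] = (stats["strand_bias"] >= th.max_strand_bias).fillna(False).to_numpy()
    else:
        skipped.append("strand_bias")
    reasons["frr"] = (stats["frr"] <= th.min_frr).to_numpy()
    reasons["coverage_high"] = (cov_ratio >= th.max_coverage_ratio).to_numpy()
    reasons["coverage_low"] = (cov_ratio <= th.min_coverage_ratio).to_numpy()
    reasons["phased_fraction"] = (stats["phased_fraction"] < th.min_phased_fraction).to_numpy()

    if snps is not None and len(snps) > 0:
        common = snps[snps["maf"] > th.snp_maf]
        near = np.zeros(n, dtype=bool)
        for chrom, grp in common.groupby("chrom"):
            mask = stats["chrom"] == chrom
            if not mask.any():
                continue
            pos = np.sort(grp["pos"].to_numpy())
            starts = stats.loc[mask, "start"].to_numpy()
            ends = stats.loc[mask, "end"].to_numpy()
            # distance from interval [start, end) to nearest SNP position
            idx = np.searchsorted(pos, starts)
            dist = np.full(mask.sum(), np.inf)
            left = idx - 1
            ok = left >= 0
            dist[ok] = starts[ok] - pos[left[ok]]
            right = np.searchsorted(pos, ends - 1)
            inside = (idx < len(pos)) & (pos[np.minimum(idx, len(pos) - 1)] <= ends - 1)
            dist[inside] = 0
            after = np.minimum(right, len(pos) - 1)
            d_after = pos[after] - (ends - 1)
            dist = np.minimum(dist, np.where(d_after >= 0, d_after, np.inf))
            near[np.flatnonzero(mask.to_numpy())] = dist <= th.snp_distance
        reasons["near_snp"] = near

    if dark_regions is not None and len(dark_regions) > 0:
        dark = np.zeros(n, dtype=bool)
        for chrom, grp in dark_regions.groupby("chrom"):
            mask = stats["chrom"] == chrom
            if not mask.any():
                continue
            starts = stats.loc[mask, "start"].to_numpy()
            ends = stats.loc[mask, "end"].to_numpy()
            hit = np.zeros(mask.sum(), dtype=bool)
            for _, row in grp.iterrows():
                hit |= (starts < row["end"]) & (ends > row["start"])
            dark[np.flatnonzero(mask.to_numpy())] = hit
        reasons["dark_region"] = dark

    fired = np.zeros(n, dtype=bool)
    log_rows = []
    for reason, mask in reasons.items():
        fired |= mask
        for i in np.flatnonzero(mask):
            log_rows.append(
                (stats.iloc[i]["chrom"], stats.iloc[i]["start"], stats.iloc[i]["end"], reason)
            )
    drop_log = pd.DataFrame(log_rows, columns=["chrom", "start", "end", "reason"])
    return FilterResult(kept=stats[~fired].reset_index(drop=True), drop_log=drop_log,
                        skipped_filters=skipped)
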