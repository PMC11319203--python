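"""Methylation-depleted sequence (MDS) detection and cataloging.

An MDS is a run of three or more CpG units on one parental haplotype of at
least one individual, each unit depleted of methylation (rate < 0.15 for the
unmethylated class, < 0.5 for the low-methylated class) and with successive
units no more than 500 bp apart. Runs found across the cohort are clustered
by shared CpG units and reduced to a non-redundant catalog by repeatedly
nominating the most frequently occurring run (exact unit-set identity) as
the representative MDS, removing overlapping runs, until the cluster is
empty. Frequency ties go to the longest run in bp, then the leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import UnionFind
from .qc import LOW_METHYLATED_MAX, UNMETHYLATED_MAX


@dataclass(frozen=True)
class DepletedRun:
    sample: str
    haplotype: str
    chrom: str
    unit_ids: tuple  # ordered (start, end) pairs
    mds_class: str

    @property
    def start(self) -> int:
        return self.unit_ids[0][0]

    @property
    def end(self) -> int:
        return self.unit_ids[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class MdsRecord:
    mds_id: str
    chrom: str
    start: int
    end: int
    unit_ids: tuple
    mds_class: str
    frequency: int
    cluster_id: int


def _scan_one(units: pd.DataFrame, threshold: float, min_units: int, max_gap: int):
    """Maximal blocks of consecutive measured units with rate < threshold.

    ``units`` is one (sample, haplotype, chrom) group, already restricted to
    measured units (depth filter applied by the caller), sorted by start.
    A measured unit at or above the threshold breaks a run even when the
    next depleted unit is within ``max_gap``; a gap > ``max_gap`` between
    successive depleted units also breaks it.
    """
    starts = units["start"].to_numpy()
    ends = units["end"].to_numpy()
    rates = units["rate"].to_numpy()
    blocks = []
    current: list[int] = []
    for i in range(len(units)):
        if rates[i] < threshold:
            if current and starts[i] - starts[current[-1]] > max_gap:
                blocks.append(current)
                current = []
            current.append(i)
        else:
            if current:
                blocks.append(current)
            current = []
    if current:
        blocks.append(current)
    return [
        tuple((int(starts[i]), int(ends[i])) for i in b)
        for b in blocks
        if len(b) >= min_units
    ]


def find_depleted_runs(
    rates: pd.DataFrame,
    min_units: int = 3,
    max_gap: int = 500,
    min_reads: int = 10,
    unmethylated_threshold: float = UNMETHYLATED_MAX,
    low_threshold: float = LOW_METHYLATED_MAX,
) -> list[DepletedRun]:
    """Find per-haplotype methylation-depleted runs across a cohort.

    ``rates`` is the long per-unit table from :func:`haplomethyl.qc.aggregate_calls`
    (columns chrom, start, end, sample, haplotype, rate, n_reliable). Units
    with fewer than ``min_reads`` reliable reads are removed before
    scanning and are invisible to the gap rule. Low-methylated runs
    (rate < 0.5) are emitted only where no unmethylated run of the same
    sample/haplotype overlaps them.
    """
    measured = rates[rates["n_reliable"] >= min_reads]
    runs: list[DepletedRun] = []
    for (sample, hap, chrom), grp in measured.groupby(
        ["sample", "haplotype", "chrom"], observed=True, sort=True
    ):
        starts = grp["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
        if np.any(np.diff(starts) == 0):
            raise ValueError(f"duplicate unit positions for {sample}/{hap}/{chrom}")
        un_blocks = _scan_one(grp, unmethylated_threshold, min_units, max_gap)
        un_units = {u for b in un_blocks for u in b}
        for b in un_blocks:
            runs.append(DepletedRun(sample, hap, chrom, b, "unmethylated"))
        for b in _scan_one(grp, low_threshold, min_units, max_gap):
            if not any(u in un_units for u in b):
                runs.append(DepletedRun(sample, hap, chrom, b, "low_methylated"))
    return runs


def _flank_ok(run: DepletedRun, unit_index: dict, depth: dict, min_flank_reads: int) -> bool:
    """The units immediately up/downstream of the run must be measured deeply.

    ``unit_index`` maps chrom -> sorted array of (start, end) unit pairs;
    ``depth`` maps (chrom, start, sample, haplotype) -> reliable read count.
    A flank that does not exist (run at the edge of the measured genome)
    passes vacuously.
    """
    units = unit_index[run.chrom]
    starts = [u[0] for u in units]
    i_first = starts.index(run.unit_ids[0][0])
    i_last = starts.index(run.unit_ids[-1][0])
    for j in (i_first - 1, i_last + 1):
        if 0 <= j < len(units):
            n = depth.get((run.chrom, units[j][0], run.sample, run.haplotype), 0)
            if n <= min_flank_reads:
                return False
    return True


def _cluster_runs(runs: list[DepletedRun]) -> list[list[DepletedRun]]:
    """Transitive clustering of runs by shared CpG units."""
    uf = UnionFind(len(runs))
    owner: dict = {}
    for i, run in enumerate(runs):
        for u in run.unit_ids:
            key = (run.chrom, u)
            if key in owner:
                uf.union(i, owner[key])
            else:
                owner[key] = i
    clusters: dict[int, list[DepletedRun]] = {}
    for i, run in enumerate(runs):
        clusters.setdefault(uf.find(i), []).append(run)
    return list(clusters.values())


def _catalog_cluster(cluster: list[DepletedRun], cluster_id: int) -> list[MdsRecord]:
    """Greedy most-frequent cataloging of one cluster of runs."""
    remaining = list(cluster)
    records = []
    while remaining:
        freq: dict = {}
        for run in remaining:
            freq[run.unit_ids] = freq.get(run.unit_ids, 0) + 1
        # most frequent; ties -> longest bp span; then leftmost start
        best = max(
            freq,
            key=lambda u: (freq[u], u[-1][1] - u[0][0], -u[0][0]),
        )
        rep = next(r for r in remaining if r.unit_ids == best)
        records.append(
            MdsRecord(
                mds_id="",
                chrom=rep.chrom,
                start=best[0][0],
                end=best[-1][1],
                unit_ids=best,
                mds_class=rep.mds_class,
                frequency=freq[best],
                cluster_id=cluster_id,
            )
        )
        best_units = set(best)
        remaining = [r for r in remaining if not any(u in best_units for u in r.unit_ids)]
    return records


def select_mds(
    runs: list[DepletedRun],
    unit_depth: pd.DataFrame | None = None,
    min_flank_reads: int = 10,
) -> list[MdsRecord]:
    """Reduce cohort runs to the non-redundant MDS catalog.

    Unmethylated runs are cataloged first; low-methylated runs are processed
    in a second pass restricted to coordinates not covered by an
    unmethylated MDS. ``unit_depth`` (optional) is the long rate table used
    to apply the flank rule: a run is dropped if the unit immediately up- or
    downstream exists but has <= ``min_flank_reads`` reliable reads on that
    sample/haplotype.
    """
    depth: dict = {}
    unit_index: dict = {}
    if unit_depth is not None:
        for row in unit_depth.itertuples(index=False):
            depth[(row.chrom, row.start, row.sample, row.haplotype)] = row.n_reliable
        for chrom, grp in unit_depth.groupby("chrom", observed=True):
            unit_index[chrom] = sorted(set(zip(grp["start"], grp["end"])))

    def passes_flank(run: DepletedRun) -> bool:
        if unit_depth is None or run.chrom not in unit_index:
            return True
        return _flank_ok(run, unit_index, depth, min_flank_reads)

    records: list[MdsRecord] = []
    cluster_id = 0
    cataloged_units: set = set()
    for mds_class in ("unmethylated", "low_methylated"):
        class_runs = [r for r in runs if r.mds_class == mds_class and passes_flank(r)]
        if mds_class == "low_methylated":
            class_runs = [
                r
                for r in class_runs
                if not any((r.chrom, u) in cataloged_units for u in r.unit_ids)
            ]
        for cluster in _cluster_runs(class_runs):
            recs = _catalog_cluster(cluster, cluster_id)
            records.extend(recs)
            cluster_id += 1
        if mds_class == "unmethylated":
            for rec in records:
                cataloged_units.update((rec.chrom, u) for u in rec.unit_ids)
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    for i, rec in enumerate(records):
        rec.mds_id = f"MDS_{i:05d}"
    return records


def mds_methylation_rate(
    mds: MdsRecord,
    unit_counts: pd.DataFrame,
    min_calls: int = 1,
) -> pd.DataFrame:
    """5-mCpG rate of one MDS for every (sample, haplotype) in the cohort.

    Pools reliable read-level calls over the MDS's units:
    rate = methylated / (methylated + unmethylated). Rates based on fewer
    than ``min_calls`` reliable calls are NaN. Computed cohort-wide, not
    only for the discovery subset.
    """
    unit_starts = {u[0] for u in mds.unit_ids}
    sub = unit_counts[
        (unit_counts["chrom"] == mds.chrom) & (unit_counts["start"].isin(unit_starts))
    ]
    agg = (
        sub.groupby(["sample", "haplotype"], observed=True)
        .agg(n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum"))
        .reset_index()
    )
    agg["n_calls"] = agg["n_meth"] + agg["n_unmeth"]
    with np.errstate(invalid="ignore"):
        agg["rate"] = np.where(
            agg["n_calls"] >= max(min_calls, 1), agg["n_meth"] / agg["n_calls"], np.nan
        )
    agg.insert(0, "mds_id", mds.mds_id)
    return agg


def mds_rate_matrix(
    catalog: list[MdsRecord], unit_counts: pd.DataFrame, min_calls: int = 1
) -> pd.DataFrame:
    """Long-format MDS x (sample, haplotype) rate table for a whole catalog."""
    parts = [mds_methylation_rate(m, unit_counts, min_calls) for m in catalog]
    if not parts:
        return pd.DataFrame(
            columns=["mds_id", "sample", "haplotype", "n_meth", "n_unmeth", "n_calls", "rate"]
        )
    return pd.concat(parts, ignore_index=True)


def catalog_to_bed(catalog: list[MdsRecord]) -> pd.DataFrame:
    """BED6+3 representation of an MDS catalog."""
    rows = [
        (
            m.chrom,
            m.start,
            m.end,
            m.mds_id,
            m.frequency,
            ".",
            m.mds_class,
            len(m.unit_ids),
            ",".join(f"{s}-{e}" for s, e in m.unit_ids),
        )
        for m in catalog
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "mds_class", "n_units", "unit_ids"],
    )
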