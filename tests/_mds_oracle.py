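"""Independent brute-force MDS cataloger used as a test oracle.

Deliberately coded on different foundations than the package's caller:
run scanning with explicit index walking, clustering via a networkx
overlap graph, frequency counting with collections.Counter, and the
greedy selection as literal repeated max-search over the remaining runs.
"""

from collections import Counter

import networkx as nx


def oracle_runs(rate_table, threshold, min_units=3, max_gap=500, min_reads=10):
    """All maximal depleted runs, as (sample, hap, chrom, unit tuple)."""
    out = []
    keys = rate_table[["sample", "haplotype", "chrom"]].drop_duplicates()
    for _, key in keys.iterrows():
        sub = rate_table[
            (rate_table["sample"] == key["sample"])
            & (rate_table["haplotype"] == key["haplotype"])
            & (rate_table["chrom"] == key["chrom"])
            & (rate_table["n_reliable"] >= min_reads)
        ].sort_values("start")
        units = list(zip(sub["start"], sub["end"], sub["rate"]))
        i = 0
        while i < len(units):
            if units[i][2] >= threshold:
                i += 1
                continue
            j = i
            while (
                j + 1 < len(units)
                and units[j + 1][2] < threshold
                and units[j + 1][0] - units[j][0] <= max_gap
            ):
                j += 1
            if j - i + 1 >= min_units:
                out.append(
                    (key["sample"], key["haplotype"], key["chrom"],
                     tuple((int(s), int(e)) for s, e, _ in units[i:j + 1]))
                )
            i = j + 1
    return out


def oracle_class_runs(rate_table, min_units=3, max_gap=500, min_reads=10):
    """(run, class) pairs; low-methylated only where unmethylated absent."""
    un = oracle_runs(rate_table, 0.15, min_units, max_gap, min_reads)
    low = oracle_runs(rate_table, 0.50, min_units, max_gap, min_reads)
    out = [(r, "unmethylated") for r in un]
    for r in low:
        s, h, c, units = r
        covered = set()
        for s2, h2, c2, units2 in un:
            if (s2, h2, c2) == (s, h, c):
                covered.update(units2)
        if not any(u in covered for u in units):
            out.append((r, "low_methylated"))
    return out


def _flank_passes(run_units, chrom, sample, hap, rate_table, min_flank_reads=10):
    chrom_units = sorted(
        set(zip(rate_table.loc[rate_table["chrom"] == chrom, "start"],
                rate_table.loc[rate_table["chrom"] == chrom, "end"]))
    )
    first = chrom_units.index(run_units[0])
    last = chrom_units.index(run_units[-1])
    neighbours = []
    if first > 0:
        neighbours.append(chrom_units[first - 1])
    if last < len(chrom_units) - 1:
        neighbours.append(chrom_units[last + 1])
    for start, end in neighbours:
        row = rate_table[
            (rate_table["chrom"] == chrom)
            & (rate_table["start"] == start)
            & (rate_table["sample"] == sample)
            & (rate_table["haplotype"] == hap)
        ]
        n = int(row["n_reliable"].iloc[0]) if len(row) else 0
        if n <= min_flank_reads:
            return False
    return True


def _greedy(class_runs):
    """Repeated most-frequent selection within connected overlap components."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(class_runs)))
    for i in range(len(class_runs)):
        for j in range(i + 1, len(class_runs)):
            (si, hi, ci, ui), _ = class_runs[i]
            (sj, hj, cj, uj), _ = class_runs[j]
            if ci == cj and set(ui) & set(uj):
                graph.add_edge(i, j)
    catalog = []
    for component in nx.connected_components(graph):
        pool = [class_runs[i] for i in component]
        while pool:
            counts = Counter(run[3] for run, _ in pool)
            best, best_key = None, None
            for units, freq in counts.items():
                key = (freq, units[-1][1] - units[0][0], -units[0][0])
                if best_key is None or key > best_key:
                    best, best_key = units, key
            cls = next(c for (run, c) in pool if run[3] == best)
            chrom = next(run[2] for (run, c) in pool if run[3] == best)
            catalog.append((chrom, best[0][0], best[-1][1], best, cls, counts[best]))
            pool = [(run, c) for (run, c) in pool if not set(run[3]) & set(best)]
    return catalog


def oracle_catalog(rate_table, min_units=3, max_gap=500, min_reads=10,
                   min_flank_reads=10, apply_flank=True):
    """Full brute-force catalog: runs -> flank rule -> classes -> greedy."""
    class_runs = oracle_class_runs(rate_table, min_units, max_gap, min_reads)
    if apply_flank:
        class_runs = [
            ((s, h, c, u), cls)
            for (s, h, c, u), cls in class_runs
            if _flank_passes(u, c, s, h, rate_table, min_flank_reads)
        ]
    un = _greedy([cr for cr in class_runs if cr[1] == "unmethylated"])
    cataloged_units = {(c, u) for c, _, _, units, _, _ in un for u in units}
    low_runs = [
        cr for cr in class_runs
        if cr[1] == "low_methylated"
        and not any((cr[0][2], u) in cataloged_units for u in cr[0][3])
    ]
    return sorted(un + _greedy(low_runs))
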