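"""MDS run detection, greedy cataloging, and rate measurement."""

import numpy as np
import pandas as pd
import pytest

import haplomethyl as hm
from haplomethyl.mds import DepletedRun

from _mds_oracle import oracle_catalog


def rate_table(rows):
    """rows: (chrom, start, sample, hap, rate, n_reliable); end = start + 10."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "sample", "haplotype", "rate",
                                     "n_reliable"])
    df["end"] = df["start"] + 10
    df["n_meth"] = (df["rate"] * df["n_reliable"]).round().astype(int)
    df["n_unmeth"] = df["n_reliable"] - df["n_meth"]
    return df


class TestFindDepletedRuns:
    def test_simple_run(self):
        rows = [("chr1", 1000 + 200 * i, "s1", "P", r, 15)
                for i, r in enumerate([0.05, 0.10, 0.14])]
        runs = hm.find_depleted_runs(rate_table(rows))
        assert len(runs) == 1
        assert runs[0].mds_class == "unmethylated"
        assert len(runs[0].unit_ids) == 3

    def test_high_rate_breaks_run(self):
        rows = [("chr1", 1000 + 200 * i, "s1", "P", r, 15)
                for i, r in enumerate([0.05, 0.16, 0.05, 0.05, 0.05])]
        runs = [r for r in hm.find_depleted_runs(rate_table(rows))
                if r.mds_class == "unmethylated"]
        assert len(runs) == 1
        assert [u[0] for u in runs[0].unit_ids] == [1400, 1600, 1800]

    def test_gap_over_500_splits(self):
        starts = [1000, 1200, 1800, 2000]  # 600-bp gap after the second unit
        rows = [("chr1", s, "s1", "P", 0.05, 15) for s in starts]
        runs = [r for r in hm.find_depleted_runs(rate_table(rows))
                if r.mds_class == "unmethylated"]
        assert runs == []

    def test_low_depth_units_invisible(self):
        rows = [("chr1", 1000 + 200 * i, "s1", "P", 0.05, n)
                for i, n in enumerate([15, 5, 15, 15])]
        runs = [r for r in hm.find_depleted_runs(rate_table(rows))
                if r.mds_class == "unmethylated"]
        # unit 2 removed pre-scan; remaining three chain across its position
        assert len(runs) == 1
        assert len(runs[0].unit_ids) == 3

    def test_low_methylated_excluded_where_unmethylated(self):
        rows = [("chr1", 1000 + 200 * i, "s1", "P", 0.05, 15) for i in range(3)]
        runs = hm.find_depleted_runs(rate_table(rows))
        classes = {r.mds_class for r in runs}
        assert classes == {"unmethylated"}

    def test_low_methylated_emitted_alone(self):
        rows = [("chr1", 1000 + 200 * i, "s1", "P", 0.3, 15) for i in range(3)]
        runs = hm.find_depleted_runs(rate_table(rows))
        assert {r.mds_class for r in runs} == {"low_methylated"}


class TestSelectMds:
    def mk_run(self, sample, units, cls="unmethylated"):
        return DepletedRun(sample, "P", "chr1",
                           tuple((1000 + 200 * u, 1010 + 200 * u) for u in units), cls)

    def test_greedy_most_frequent(self):
        runs = [self.mk_run("s1", [3, 4, 5, 6]), self.mk_run("s2", [3, 4, 5, 6]),
                self.mk_run("s3", [2, 3, 4])]
        catalog = hm.select_mds(runs)
        assert len(catalog) == 1
        assert catalog[0].frequency == 2
        assert catalog[0].start == 1000 + 200 * 3

    def test_tie_goes_to_longest(self):
        runs = [self.mk_run("s1", [1, 2, 3]), self.mk_run("s2", [2, 3, 4, 5])]
        catalog = hm.select_mds(runs)
        assert len(catalog) == 1
        assert len(catalog[0].unit_ids) == 4

    def test_disjoint_clusters_independent(self):
        runs = [self.mk_run("s1", [1, 2, 3]), self.mk_run("s2", [10, 11, 12])]
        catalog = hm.select_mds(runs)
        assert len(catalog) == 2

    def test_cataloged_mds_pairwise_unit_disjoint(self):
        rng = np.random.default_rng(3)
        runs = []
        for i in range(40):
            a = int(rng.integers(0, 20))
            runs.append(self.mk_run(f"s{i}", list(range(a, a + int(rng.integers(3, 7))))))
        catalog = hm.select_mds(runs)
        for i, m1 in enumerate(catalog):
            for m2 in catalog[i + 1:]:
                assert not set(m1.unit_ids) & set(m2.unit_ids)

    def test_every_run_covered_or_flank_dropped(self):
        rng = np.random.default_rng(4)
        runs = []
        for i in range(30):
            a = int(rng.integers(0, 15))
            runs.append(self.mk_run(f"s{i}", list(range(a, a + 4))))
        catalog = hm.select_mds(runs)
        for run in runs:
            assert any(set(run.unit_ids) & set(m.unit_ids) for m in catalog)

    def test_flank_rule_drops_shallow_neighbourhood(self):
        rows = [("chr1", 1000 + 200 * i, "s1", "P", r, n)
                for i, (r, n) in enumerate(
                    [(0.9, 5), (0.05, 15), (0.05, 15), (0.05, 15), (0.9, 15)]
                )]
        table = rate_table(rows)
        runs = hm.find_depleted_runs(table)
        catalog = hm.select_mds(runs, table)
        # upstream flank has 5 <= 10 reads -> run dropped
        assert catalog == []
        catalog_no_flank = hm.select_mds(runs)
        assert len(catalog_no_flank) == 1


def random_instance(rng):
    """Random small cohort rate table for the oracle cross-check."""
    n_units = int(rng.integers(5, 31))
    n_samples = int(rng.integers(1, 13))
    gaps = rng.choice([100, 300, 450, 600], size=n_units - 1,
                      p=[0.4, 0.3, 0.2, 0.1])
    starts = np.concatenate([[1000], 1000 + np.cumsum(gaps + 10)])
    rows = []
    for s in range(n_samples):
        for hap in ("P", "M"):
            depleted = rng.random() < 0.7
            anchor = int(rng.integers(0, n_units))
            width = int(rng.integers(2, 8))
            for i, st in enumerate(starts):
                if depleted and anchor <= i < anchor + width:
                    rate = float(rng.choice([0.02, 0.08, 0.3], p=[0.5, 0.3, 0.2]))
                else:
                    rate = float(rng.choice([0.02, 0.3, 0.85, 0.95],
                                            p=[0.1, 0.1, 0.4, 0.4]))
                n_rel = int(rng.choice([4, 9, 10, 11, 20, 30],
                                       p=[0.08, 0.07, 0.05, 0.2, 0.4, 0.2]))
                rows.append(("chr1", int(st), f"s{s}", hap, rate, n_rel))
    return rate_table(rows)


def catalog_as_set(catalog):
    return sorted(
        (m.chrom, m.start, m.end, m.unit_ids, m.mds_class, m.frequency) for m in catalog
    )


@pytest.mark.parametrize("seed_block", range(4))
def test_oracle_equivalence_random_instances(seed_block):
    """Greedy catalog matches a brute-force implementation on random cohorts."""
    rng = np.random.default_rng(1234 + seed_block)
    for _ in range(15):
        table = random_instance(rng)
        catalog = hm.select_mds(hm.find_depleted_runs(table), table)
        expected = oracle_catalog(table)
        assert catalog_as_set(catalog) == sorted(expected)


class TestMdsRate:
    def test_pooled_read_level_counts(self):
        mds = hm.MdsRecord("m1", "chr1", 1000, 1410, ((1000, 1010), (1200, 1210),
                                                      (1400, 1410)),
                           "unmethylated", 1, 0)
        counts = pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [1000, 1200, 1400],
            "sample": ["s1"] * 3,
            "haplotype": ["P"] * 3,
            "n_meth": [2, 3, 0],
            "n_unmeth": [0, 0, 3],
        })
        out = hm.mds_methylation_rate(mds, counts)
        assert out["rate"].iloc[0] == pytest.approx(5 / 8)

    def test_all_unmethylated_zero(self):
        mds = hm.MdsRecord("m1", "chr1", 1000, 1010, ((1000, 1010),),
                           "unmethylated", 1, 0)
        counts = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "sample": ["s1"],
                               "haplotype": ["P"], "n_meth": [0], "n_unmeth": [7]})
        assert hm.mds_methylation_rate(mds, counts)["rate"].iloc[0] == 0.0

    def test_no_reliable_calls_missing(self):
        mds = hm.MdsRecord("m1", "chr1", 1000, 1010, ((1000, 1010),),
                           "unmethylated", 1, 0)
        counts = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "sample": ["s1"],
                               "haplotype": ["P"], "n_meth": [0], "n_unmeth": [0]})
        assert np.isnan(hm.mds_methylation_rate(mds, counts)["rate"].iloc[0])


def test_planted_region_recovery(small_cohort, small_rates):
    """Planted depleted regions are recovered with high sensitivity/precision."""
    catalog = hm.select_mds(hm.find_depleted_runs(small_rates), small_rates)

    def overlaps(m, p):
        return m.chrom == p[1] and m.start < p[3] and m.end > p[2]

    planted = small_cohort.truth.planted_mds
    sens = np.mean([any(overlaps(m, p) for m in catalog) for p in planted])
    prec = np.mean([any(overlaps(m, p) for p in planted) for m in catalog])
    assert sens >= 0.8
    assert prec >= 0.9
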