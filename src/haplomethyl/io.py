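"""Readers and writers for the package's plain-text interchange formats.

All genomic coordinates are 0-based half-open internally; BED output is
written natively in that convention and the genotype TSV carries 1-based
positions (converted at the boundary), mirroring VCF habit. Haplotype
order is paternal first, maternal second, always carried as an explicit
column or a ``p|m`` allele pair, never positionally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .asmqtl import HaplotypeGenotypes

CALL_COLUMNS = ["chrom", "unit_start", "unit_end", "n_sites",
                "sample_id", "read_id", "haplotype", "llr"]


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, columns=CALL_COLUMNS)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"chrom": "category", "sample_id": "category", "haplotype": "category",
               "llr": np.float32},
    )


def write_genotypes(genotypes: HaplotypeGenotypes, path) -> None:
    """Genotype TSV: variant metadata plus one ``p|m`` column per sample."""
    v = genotypes.variants
    out = pd.DataFrame(
        {
            "variant_id": v["variant_id"],
            "chrom": v["chrom"],
            "pos": v["pos"] + 1,  # 1-based on disk
            "ref": "A",
            "alt": "B",
            "maf": v["maf"],
        }
    )
    a = genotypes.alleles
    for j, sample in enumerate(genotypes.samples):
        out[sample] = [f"{a[i, j, 0]}|{a[i, j, 1]}" for i in range(a.shape[0])]
    out.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> HaplotypeGenotypes:
    df = pd.read_csv(path, sep="\t")
    meta = ["variant_id", "chrom", "pos", "ref", "alt", "maf"]
    samples = [c for c in df.columns if c not in meta]
    alleles = np.zeros((len(df), len(samples), 2), dtype=np.int8)
    for j, sample in enumerate(samples):
        parts = df[sample].str.split("|", expand=True).astype(np.int8)
        alleles[:, j, 0] = parts[0]
        alleles[:, j, 1] = parts[1]
    variants = df[["variant_id", "chrom", "pos", "maf"]].copy()
    variants["pos"] = variants["pos"] - 1  # back to 0-based
    return HaplotypeGenotypes(alleles, variants, samples)


def write_bed(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = list(names) + [f"col{i}" for i in range(len(names), df.shape[1])]
    return df


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
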