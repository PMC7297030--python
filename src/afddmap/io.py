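"""Reading and writing the pipeline's table formats.

Per-pool variant tables travel either as a TSV dialect (chrom, pos, ref, alt,
depth, alt_count, af) or as minimal single-sample VCF v4.2 with DP and AD in
FORMAT.  Peak regions are written as BED6.  All writers produce byte-stable
output for a given table.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

POOL_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_count", "af"]


def write_pool_tsv(df: pd.DataFrame, path) -> None:
    out = df[POOL_COLUMNS].copy()
    out["af"] = out["af"].map(lambda x: "" if pd.isna(x) else f"{x:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_pool_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "pos": np.int64, "ref": str, "alt": str,
               "depth": np.int64, "alt_count": np.int64, "af": float},
    )
    missing = set(POOL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pool TSV {path} lacks column(s) {sorted(missing)}")
    return df[POOL_COLUMNS]


def write_pool_vcf(
    df: pd.DataFrame, path, sample: str, contigs: Mapping[str, int] | None = None
) -> None:
    """Minimal single-sample VCF v4.2 with per-site DP and AD (ref, alt)."""
    lines = ["##fileformat=VCFv4.2", "##source=afddmap"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={int(length)}>")
    lines += [
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths (ref, alt)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for row in df.itertuples(index=False):
        depth = int(row.depth)
        alt_count = int(row.alt_count)
        lines.append(
            f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
            f"DP:AD\t{depth}:{depth - alt_count},{alt_count}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pool_vcf(path) -> pd.DataFrame:
    """Read a single-sample VCF carrying DP and AD into the pool-table layout."""
    vcf = VCF(os.fspath(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected a single-sample pool VCF")
    rows = []
    for v in vcf:
        ad = v.format("AD")
        dp = v.format("DP")
        if ad is None or dp is None:
            raise ValueError(f"{path}: record {v.CHROM}:{v.POS} lacks DP/AD")
        depth = int(dp[0][0])
        alt_count = int(ad[0][1])
        af = 100.0 * alt_count / depth if depth > 0 else np.nan
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": int(v.POS),
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "depth": depth,
                "alt_count": alt_count,
                "af": af,
            }
        )
    vcf.close()
    return pd.DataFrame(rows, columns=POOL_COLUMNS)


def read_pool_table(path) -> pd.DataFrame:
    """Dispatch on extension: ``.vcf`` or the TSV dialect."""
    if str(path).endswith(".vcf"):
        return read_pool_vcf(path)
    return read_pool_tsv(path)


def write_chrom_lengths(lengths: Mapping[str, int], path) -> None:
    pd.DataFrame(
        {"chrom": list(lengths), "length": [int(v) for v in lengths.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_chrom_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length": np.int64})
    if not {"chrom", "length"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns chrom, length")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED6: name = contributing type sets, score = round(10 * apex LODz)."""
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            name = row.contributing_types.replace("/", "") or "peak"
            score = int(round(10 * row.apex_lodz))
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{name}\t{score}\t.\n"
            )


def write_truth_bed(truth_loci: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in truth_loci.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.pos) - 1}\t{int(row.pos)}\t{row.name}\n")
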