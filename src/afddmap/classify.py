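"""Variant-table QC, pool partitioning and zygosity grouping.

Operates on per-pool variant tables with columns ``chrom, pos, ref, alt,
depth, alt_count, af`` (``af`` in percent).  QC reproduces the caller-level
thresholds (minimum coverage 10, minimum variant-read count 2) followed by
removal of reference-allele calls, non-SNVs and sites of coverage below 20x
or above 200x.  Pool-common SNVs are then grouped by zygosity in each pool:
heterozygous for 15% <= AF < 85%, homozygous for AF >= 85%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "MalformedRecordError",
    "DuplicateSiteError",
    "qc_filter",
    "partition_pools",
    "zygosity_group",
    "GROUPS",
    "HET_MIN_AF",
    "HOM_MIN_AF",
]

SITE_KEY = ["chrom", "pos", "ref", "alt"]

HET_MIN_AF = 15.0
HOM_MIN_AF = 85.0

#: zygosity groups of a pool-common SNV (R = recessive pool, D = dominant pool)
GROUPS = ("Ho-R/He-D", "He-R/He-D", "He-R/Ho-D", "Ho-R/Ho-D", "ungrouped")


class MalformedRecordError(ValueError):
    """A variant record violates basic consistency (e.g. alt_count > depth)."""


class DuplicateSiteError(ValueError):
    """The same (chrom, pos, ref, alt) key occurs twice within one pool."""


@dataclass(frozen=True)
class QCThresholds:
    call_min_coverage: int = 10
    call_min_alt_count: int = 2
    keep_min_coverage: int = 20
    keep_max_coverage: int = 200
    snv_only: bool = True
    drop_reference_calls: bool = True

    def __post_init__(self) -> None:
        if self.keep_min_coverage < self.call_min_coverage:
            raise ValueError("keep_min_coverage must be >= call_min_coverage")
        if self.keep_max_coverage <= self.keep_min_coverage:
            raise ValueError("keep_max_coverage must be > keep_min_coverage")


def qc_filter(
    records: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the QC rules in order; return surviving records and a removal tally.

    The tally keys, in application order: ``call_coverage`` (< 10 reads),
    ``call_alt_count`` (< 2 variant reads), ``reference_call`` (the called
    allele is the reference), ``non_snv``, ``coverage_low`` (< 20x),
    ``coverage_high`` (> 200x).  Malformed records (alt_count > depth, or
    negative counts) raise :class:`MalformedRecordError` rather than being
    dropped silently.
    """
    df = records.copy()
    bad = (
        (df["alt_count"] > df["depth"])
        | (df["alt_count"] < 0)
        | (df["depth"] < 0)
    )
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise MalformedRecordError(
            f"{int(bad.sum())} record(s) with alt_count > depth or negative "
            f"counts (first rows: {rows})"
        )

    tally: dict[str, int] = {}

    def drop(name: str, mask: pd.Series) -> None:
        nonlocal df
        tally[name] = int(mask.sum())
        df = df[~mask]

    drop("call_coverage", df["depth"] < thresholds.call_min_coverage)
    drop("call_alt_count", df["alt_count"] < thresholds.call_min_alt_count)
    if thresholds.drop_reference_calls:
        ref_call = (df["alt"] == df["ref"]) | df["alt"].isin([".", ""])
        drop("reference_call", ref_call)
    else:
        tally["reference_call"] = 0
    if thresholds.snv_only:
        is_snv = (
            df["ref"].str.len().eq(1)
            & df["alt"].str.len().eq(1)
            & df["ref"].str.upper().isin(list("ACGT"))
            & df["alt"].str.upper().isin(list("ACGT"))
            & (df["ref"] != df["alt"])
        )
        drop("non_snv", ~is_snv)
    else:
        tally["non_snv"] = 0
    drop("coverage_low", df["depth"] < thresholds.keep_min_coverage)
    drop("coverage_high", df["depth"] > thresholds.keep_max_coverage)
    return df.reset_index(drop=True), tally


def _check_unique(df: pd.DataFrame, name: str) -> None:
    dup = df.duplicated(subset=SITE_KEY)
    if dup.any():
        first = df.loc[dup.idxmax(), SITE_KEY].tolist()
        raise DuplicateSiteError(f"duplicate site key in {name} pool: {first}")


def partition_pools(
    recessive_records: pd.DataFrame, dominant_records: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split QC-filtered records into pool-specific and pool-common sets.

    Site identity is the full (chrom, pos, ref, alt) key, so a tri-allelic
    position yields two pool-specific records rather than a spurious common
    one.  The common table pairs both pools' measurements with ``_r`` / ``_d``
    suffixes on the per-pool columns.
    """
    _check_unique(recessive_records, "recessive")
    _check_unique(dominant_records, "dominant")
    merged = recessive_records.merge(
        dominant_records, on=SITE_KEY, how="outer", suffixes=("_r", "_d"),
        indicator=True,
    )
    spec_r = merged[merged["_merge"] == "left_only"]
    spec_d = merged[merged["_merge"] == "right_only"]
    common = merged[merged["_merge"] == "both"]

    def _single(df: pd.DataFrame, suffix: str) -> pd.DataFrame:
        cols = SITE_KEY + [f"depth{suffix}", f"alt_count{suffix}", f"af{suffix}"]
        out = df[cols].copy()
        out.columns = SITE_KEY + ["depth", "alt_count", "af"]
        out[["depth", "alt_count"]] = out[["depth", "alt_count"]].astype(np.int64)
        return out.reset_index(drop=True)

    common = common.drop(columns="_merge").reset_index(drop=True)
    for col in ("depth_r", "alt_count_r", "depth_d", "alt_count_d"):
        common[col] = common[col].astype(np.int64)
    return _single(spec_r, "_r"), _single(spec_d, "_d"), common


def _zygosity(af: pd.Series) -> pd.Series:
    out = pd.Series("low-frequency", index=af.index, dtype=object)
    out[(af >= HET_MIN_AF) & (af < HOM_MIN_AF)] = "heterozygous"
    out[af >= HOM_MIN_AF] = "homozygous"
    return out


def zygosity_group(common: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label pool-common SNVs with per-pool zygosity and the four Ho/He groups.

    SNVs below the 15% heterozygote floor in either pool fall into
    ``ungrouped``.  Returns the labelled table and group tallies that
    partition the common set.
    """
    df = common.copy()
    zr = _zygosity(df["af_r"])
    zd = _zygosity(df["af_d"])
    df["zygosity_r"] = zr
    df["zygosity_d"] = zd
    group = pd.Series("ungrouped", index=df.index, dtype=object)
    group[(zr == "homozygous") & (zd == "heterozygous")] = "Ho-R/He-D"
    group[(zr == "heterozygous") & (zd == "heterozygous")] = "He-R/He-D"
    group[(zr == "heterozygous") & (zd == "homozygous")] = "He-R/Ho-D"
    group[(zr == "homozygous") & (zd == "homozygous")] = "Ho-R/Ho-D"
    df["group"] = group
    tallies = {g: int((group == g).sum()) for g in GROUPS}
    return df, tallies
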