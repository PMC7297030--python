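"""AFDDD genome scan: informative-SNV selection, window densities, z scores.

Informative SNVs are pool-common SNVs whose pool allele frequencies fall in a
segregation-type filter window (see :mod:`afddmap.segregation`): type A and
B/C candidates come from the Ho-R/He-D zygosity group, type D/E candidates
from He-R/He-D, and the AFDD (recessive-pool AF minus dominant-pool AF) must
be positive and inside the window.  Their counts in 1-Mb windows are compared
with the genome-average density by a standard-score test; windows with
``LODz = -log10(two-tailed p) > 2.5`` and positive z form peak regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import QCThresholds, partition_pools, qc_filter, zygosity_group
from .segregation import TypeFilterWindow, informative_filter_windows

__all__ = [
    "select_informative",
    "window_counts",
    "lodz_scores",
    "lodz_of_z",
    "call_peaks",
    "scan_pools",
    "ScanResult",
    "TYPE_SETS",
]

TYPE_SETS = ("A", "B/C", "D/E")
_TYPE_COL = {"A": "count_A", "B/C": "count_BC", "D/E": "count_DE"}


def select_informative(
    grouped: pd.DataFrame,
    windows: Sequence[TypeFilterWindow] | None = None,
) -> pd.DataFrame:
    """Assign zygosity-grouped common SNVs to segregation-type filter windows.

    Returns the subset of SNVs passing exactly one window, with ``afdd`` and
    ``type_set`` columns added.  The A and B/C windows are disjoint by their
    half-open AFDD boundary, and they draw from a different zygosity group
    than D/E, so the assignment is a partition.
    """
    if windows is None:
        windows = informative_filter_windows()
    df = grouped.copy()
    df["afdd"] = df["af_r"] - df["af_d"]
    type_set = pd.Series(pd.NA, index=df.index, dtype=object)
    for w in windows:
        in_window = np.fromiter(
            (w.contains(a, d) for a, d in zip(df["af_r"], df["afdd"])),
            dtype=bool, count=len(df),
        )
        candidate = (
            (df["group"] == w.source_group)
            & type_set.isna()
            & (df["afdd"] > 0)
            & in_window
        )
        type_set[candidate] = w.type_set
    df["type_set"] = type_set
    return df[df["type_set"].notna()].reset_index(drop=True)


def window_counts(
    snvs: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_size: int = 1_000_000,
    step: int | None = None,
) -> pd.DataFrame:
    """Count SNVs in tiling (or sliding) windows along each chromosome.

    Windows start at 0, window_size-step apart (default ``step = window_size``,
    a non-overlapping tiling under which per-chromosome counts are conserved).
    Output coordinates are 0-based half-open; input positions are 1-based.
    A trailing window shorter than ``window_size`` is kept and flagged
    ``partial``.  Per-type-set counts are included when a ``type_set`` column
    is present.
    """
    if step is None:
        step = window_size
    if window_size <= 0 or step <= 0 or step > window_size:
        raise ValueError("require 0 < step <= window_size")
    has_types = "type_set" in snvs.columns
    rows = []
    for chrom in chrom_lengths:
        length = int(chrom_lengths[chrom])
        sub = snvs[snvs["chrom"] == chrom]
        pos = np.sort(sub["pos"].to_numpy())
        if len(pos) and (pos[0] < 1 or pos[-1] > length):
            raise ValueError(f"SNV position outside {chrom} (length {length})")
        pos0 = pos - 1  # to 0-based
        type_pos = {
            t: np.sort(sub.loc[sub["type_set"] == t, "pos"].to_numpy()) - 1
            for t in TYPE_SETS
        } if has_types else {}
        start = 0
        while start < length:
            end = min(start + window_size, length)
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "count": int(
                    np.searchsorted(pos0, end, "left")
                    - np.searchsorted(pos0, start, "left")
                ),
                "partial": end - start < window_size,
            }
            for t, tp in type_pos.items():
                row[_TYPE_COL[t]] = int(
                    np.searchsorted(tp, end, "left")
                    - np.searchsorted(tp, start, "left")
                )
            rows.append(row)
            if end >= length:
                break
            start += step
    cols = ["chrom", "start", "end", "count", "partial"] + (
        [_TYPE_COL[t] for t in TYPE_SETS] if has_types else []
    )
    out = pd.DataFrame(rows, columns=cols)
    if has_types:
        # pooled homozygous-class track: the types the study found decisive
        out["count_ABC"] = out["count_A"] + out["count_BC"]
    return out


def lodz_of_z(z: float | np.ndarray) -> np.ndarray:
    """-log10 of the two-tailed standard-normal tail probability of z.

    Computed on the log scale so very large scores do not underflow.
    """
    logp = stats.norm.logsf(np.abs(z)) + np.log(2.0)
    return -logp / np.log(10.0)


def _background(counts: np.ndarray, dispersion: str, cutoff: float):
    """Background mean and sd of full-window counts under one dispersion model."""
    mean = counts.mean()
    sd = float(counts.std(ddof=1))
    if dispersion in ("clipped", "poisson"):
        # sigma-clip to convergence: windows significant under the current
        # estimate carry (candidate) signal and are excluded from background.
        # Seeded with median/IQR so that extreme peaks cannot inflate the
        # initial spread and mask themselves.
        q25, q75 = np.percentile(counts, [25, 75])
        robust_sd = (q75 - q25) / 1.349
        cur_mean, cur_sd = (
            (float(np.median(counts)), robust_sd) if robust_sd > 0 else (mean, sd)
        )
        keep = np.ones(len(counts), dtype=bool)
        for _ in range(100):
            if cur_sd <= 0:
                break
            z = (counts - cur_mean) / cur_sd
            new = (lodz_of_z(z) <= cutoff) | (z < 0)
            if new.sum() < 2:
                break
            mean = counts[new].mean()
            sd = float(counts[new].std(ddof=1))
            if (new == keep).all():
                break
            keep = new
            cur_mean, cur_sd = mean, sd
    if dispersion == "poisson":
        sd = float(np.sqrt(mean))
    return mean, sd


def lodz_scores(
    windows: pd.DataFrame,
    dispersion: str = "empirical",
    per_chromosome: bool = False,
    cutoff: float = 2.5,
    tracks: Sequence[str] = ("count",),
) -> pd.DataFrame:
    """Score window densities against the genome-average density.

    ``z = (count - mean) / sd`` with mean and sd taken over full (non-partial)
    windows; partial windows are scored but excluded from the background
    estimate.  ``dispersion`` selects the background estimate:

    - ``"empirical"``: plain mean and standard deviation across windows;
    - ``"clipped"``: sigma-clipping to convergence - windows significant under
      the current estimate are removed and mean/sd re-estimated, so the few
      windows carrying the trait signal do not inflate the background;
    - ``"poisson"``: sd = sqrt(clipped mean).

    Each entry of ``tracks`` names a count column to score; every track gets
    ``z_<track>`` / ``lodz_<track>`` columns against its own background, and
    the summary columns ``z``, ``lodz`` and ``p`` report the strongest
    positive-z track per window (with a single track they are just its score).
    ``p`` is the two-tailed normal tail probability and ``lodz = -log10(p)``.
    A zero sd yields z = 0; fewer than two background windows is an error.
    """
    if dispersion not in ("empirical", "clipped", "poisson"):
        raise ValueError(f"unknown dispersion {dispersion!r}")
    df = windows.copy()
    missing = [t for t in tracks if t not in df.columns]
    if missing:
        raise ValueError(f"window table lacks track column(s) {missing}")

    best_z = np.zeros(len(df))
    best_lodz = np.zeros(len(df))
    groups = df.groupby("chrom", sort=False) if per_chromosome else [(None, df)]
    for track in tracks:
        z = pd.Series(0.0, index=df.index)
        for _name, sub in groups:
            bg = sub.loc[~sub["partial"], track].to_numpy(dtype=float)
            if len(bg) < 2:
                raise ValueError(
                    "need at least two full windows to estimate dispersion"
                )
            mean, sd = _background(bg, dispersion, cutoff)
            if sd > 0:
                z.loc[sub.index] = (sub[track].to_numpy(dtype=float) - mean) / sd
        lz = lodz_of_z(z.to_numpy())
        suffix = "" if track == "count" else "_" + track.removeprefix("count_")
        df[f"z{suffix}" if suffix else "z_all"] = z.to_numpy()
        df[f"lodz{suffix}" if suffix else "lodz_all"] = lz
        better = (z.to_numpy() > 0) & (lz > best_lodz)
        best_lodz = np.where(better, lz, best_lodz)
        best_z = np.where(better, z.to_numpy(), best_z)
    if list(tracks) == ["count"]:
        df["z"] = df["z_all"]
        df["lodz"] = df["lodz_all"]
    else:
        df["z"] = best_z
        df["lodz"] = best_lodz
    df["p"] = np.power(10.0, -df["lodz"])
    return df


def call_peaks(
    scores: pd.DataFrame, cutoff: float = 2.5, merge_gap: int = 0
) -> pd.DataFrame:
    """Merge runs of significant windows into peak regions.

    A window is significant when ``z > 0`` and ``lodz > cutoff``; up to
    ``merge_gap`` consecutive sub-threshold windows may sit inside a region.
    The apex is the member window of maximal LODz (leftmost on ties).
    ``contributing_types`` lists the type sets whose apex-window count lies
    more than two empirical standard deviations above that type's own
    genome-wide mean (empty string when per-type counts are absent).
    """
    type_cols = [c for c in _TYPE_COL.values() if c in scores.columns]
    type_bg = {
        c: (scores.loc[~scores["partial"], c].mean(),
            scores.loc[~scores["partial"], c].std(ddof=1))
        for c in type_cols
    }
    regions = []
    for chrom, sub in scores.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        sig = ((sub["z"] > 0) & (sub["lodz"] > cutoff)).to_numpy()
        sig_idx = np.flatnonzero(sig)
        if len(sig_idx) == 0:
            continue
        # split significant windows into runs, tolerating <= merge_gap
        # sub-threshold windows between consecutive members
        breaks = np.flatnonzero(np.diff(sig_idx) > merge_gap + 1)
        run_bounds = zip(
            np.concatenate([[0], breaks + 1]),
            np.concatenate([breaks, [len(sig_idx) - 1]]),
        )
        for a, b in run_bounds:
            first, last = sig_idx[a], sig_idx[b]
            members = sub.iloc[first : last + 1]
            sig_members = members[(members["z"] > 0) & (members["lodz"] > cutoff)]
            # leftmost maximal-LODz significant window
            apex_row = sig_members.loc[sig_members["lodz"].idxmax()]
            contributing = []
            for t, col in _TYPE_COL.items():
                if col in type_bg:
                    mean, sd = type_bg[col]
                    if sd > 0 and apex_row[col] > mean + 2 * sd:
                        contributing.append(t)
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(members.iloc[0]["start"]),
                    "end": int(members.iloc[-1]["end"]),
                    "n_windows": int(len(members)),
                    "apex_start": int(apex_row["start"]),
                    "apex_end": int(apex_row["end"]),
                    "apex_lodz": float(apex_row["lodz"]),
                    "contributing_types": ",".join(contributing),
                }
            )
    return pd.DataFrame(
        regions,
        columns=[
            "chrom", "start", "end", "n_windows", "apex_start", "apex_end",
            "apex_lodz", "contributing_types",
        ],
    )


@dataclass
class ScanResult:
    """All intermediate and final products of one AFDDD scan."""

    qc_tally_recessive: dict[str, int]
    qc_tally_dominant: dict[str, int]
    n_specific_recessive: int
    n_specific_dominant: int
    n_common: int
    group_tallies: dict[str, int]
    informative_counts: dict[str, int]
    informative: pd.DataFrame
    windows: pd.DataFrame
    peaks: pd.DataFrame

    def summary(self) -> dict:
        return {
            "qc_removed": {
                "recessive": self.qc_tally_recessive,
                "dominant": self.qc_tally_dominant,
            },
            "partition": {
                "specific_recessive": self.n_specific_recessive,
                "specific_dominant": self.n_specific_dominant,
                "common": self.n_common,
            },
            "group_tallies": self.group_tallies,
            "informative_counts": self.informative_counts,
            "n_peaks": int(len(self.peaks)),
            "peaks": self.peaks.to_dict(orient="records"),
        }


def scan_pools(
    recessive_records: pd.DataFrame,
    dominant_records: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_size: int = 1_000_000,
    step: int | None = None,
    cutoff: float = 2.5,
    merge_gap: int = 1,
    thresholds: QCThresholds = QCThresholds(),
    dispersion: str = "clipped",
    per_chromosome: bool = False,
    tracks: Sequence[str] = ("count", "count_ABC"),
) -> ScanResult:
    """Full pipeline: QC -> partition -> zygosity groups -> filters -> scan.

    Defaults reflect how the mapping is actually read out: peaks are declared
    from the combined informative-SNV track *and* the pooled A + B/C track
    (the homozygous-in-recessive-pool types, which carry most of the mapping
    power and a much lower background), the background mean/sd are estimated
    with sigma-clipping so the signal windows do not inflate them, and one
    sub-threshold window is tolerated inside a peak region (``merge_gap=1``)
    since a linked region is genetically contiguous.
    """
    known = set(chrom_lengths)
    for name, df in (("recessive", recessive_records), ("dominant", dominant_records)):
        extra = set(df["chrom"].unique()) - known
        if extra:
            raise ValueError(
                f"{name} pool table contains chromosome(s) not in the genome "
                f"table: {sorted(extra)}"
            )
    rec_qc, tally_r = qc_filter(recessive_records, thresholds)
    dom_qc, tally_d = qc_filter(dominant_records, thresholds)
    spec_r, spec_d, common = partition_pools(rec_qc, dom_qc)
    grouped, group_tallies = zygosity_group(common)
    informative = select_informative(grouped)
    informative_counts = {
        t: int((informative["type_set"] == t).sum()) for t in TYPE_SETS
    }
    windows = window_counts(informative, chrom_lengths, window_size, step)
    scored = lodz_scores(windows, dispersion=dispersion,
                         per_chromosome=per_chromosome, cutoff=cutoff,
                         tracks=tracks)
    peaks = call_peaks(scored, cutoff=cutoff, merge_gap=merge_gap)
    return ScanResult(
        tally_r, tally_d, len(spec_r), len(spec_d), len(common),
        group_tallies, informative_counts, informative, scored, peaks,
    )
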