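"""Aneuploidy and local copy-number detection from read-depth tracks.

Chromosome-scale calls follow a windowed-depth recipe: mean depth in 1-kb
non-overlapping windows, removal of outlier windows (> 2× the provisional
chromosome mean), per-chromosome means, a genome-wide baseline, and a ±25%
call threshold on the relative depth. Chromosomes with a "smile" artifact —
a U-shaped depth profile with a depressed center — are summarized by their
chromosome-end depth (excluding subtelomeric margins) instead of the
whole-chromosome mean. All calls are invariant to rescaling the whole track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import DepthTrack


@dataclass
class CnvParams:
    bin_size: int = 1000
    call_threshold: float = 0.25  # ±25% of the genome mean
    outlier_factor: float = 2.0  # windows > 2× provisional chromosome mean
    smile_sd_fraction: float = 0.15  # sd > 15% of chromosome mean
    smile_dip_fraction: float = 0.15  # center > 15% below the ends
    subtelomere_margin: int = 20_000  # bp excluded at each chromosome end
    min_windows: int = 10
    genome_stat: str = "mean"  # baseline over per-chromosome effective means
    smile_correction: bool = True

    def __post_init__(self) -> None:
        if self.genome_stat not in ("mean", "median"):
            raise ValueError("genome_stat must be 'mean' or 'median'")


@dataclass
class ChromosomeDepthSummary:
    chrom: str
    sample: str
    mean_depth: float  # window mean after outlier removal
    smile_flag: bool
    effective_mean: float
    relative_depth: float
    call: str  # gain / loss / none / suppressed
    magnitude: float
    n_windows: int
    n_outlier_windows: int


def window_depth_means(track: DepthTrack, bin_size: int = 1000) -> pd.DataFrame:
    """Mean depth in non-overlapping 1-kb windows anchored at position 1.

    Partial windows (chromosome ends, or gaps in the track) are averaged
    over covered positions only; the covered fraction is reported. Windows
    with no covered positions are flagged (``n_covered`` = 0, NaN mean).
    """
    df = track.records
    widx = (df["pos"].to_numpy() - 1) // bin_size
    grouped = df.assign(widx=widx).groupby(["chrom", "widx"], sort=True)
    out = grouped["depth"].agg(["mean", "size"]).reset_index()
    out["start"] = out["widx"].astype(int) * bin_size + 1
    out["end"] = (out["widx"].astype(int) + 1) * bin_size
    out["coverage_fraction"] = out["size"] / bin_size
    return out.rename(columns={"mean": "mean_depth", "size": "n_covered"})[
        ["chrom", "start", "end", "mean_depth", "n_covered", "coverage_fraction"]
    ]


def _effective_mean(
    w: pd.DataFrame, params: CnvParams
) -> tuple[float, float, bool, int]:
    """(mean after outlier removal, effective mean, smile flag, n outliers)."""
    depths = w["mean_depth"].to_numpy(dtype=float)
    provisional = depths.mean()
    keep = depths <= params.outlier_factor * provisional
    n_out = int((~keep).sum())
    kept = w.loc[keep]
    depths = kept["mean_depth"].to_numpy(dtype=float)
    mean = depths.mean()

    # smile test: high within-chromosome variability with a depressed center
    thirds = np.array_split(np.arange(len(depths)), 3)
    smile = False
    effective = mean
    if len(depths) >= 3:
        center = depths[thirds[1]].mean()
        ends = depths[np.concatenate([thirds[0], thirds[2]])].mean()
        smile = (depths.std() > params.smile_sd_fraction * mean) and (
            center < (1.0 - params.smile_dip_fraction) * ends
        )
    if smile and params.smile_correction:
        chrom_start = int(kept["start"].min())
        chrom_end = int(kept["end"].max())
        end_thirds = kept.iloc[np.concatenate([thirds[0], thirds[2]])]
        non_subtel = end_thirds[
            (end_thirds["start"] >= chrom_start + params.subtelomere_margin)
            & (end_thirds["end"] <= chrom_end - params.subtelomere_margin)
        ]
        if len(non_subtel):
            effective = float(non_subtel["mean_depth"].mean())
    return float(mean), float(effective), bool(smile), n_out


def chromosome_summary(
    window_means: pd.DataFrame,
    sample: str = "",
    params: CnvParams | None = None,
) -> list[ChromosomeDepthSummary]:
    """Per-chromosome relative depth and aneuploidy calls for one sample.

    The genome baseline is the unweighted mean (or median, see
    ``genome_stat``) of per-chromosome effective means over chromosomes with
    at least ``min_windows`` windows; chromosomes below that get a summary
    with the call suppressed. A chromosome is called a gain when its
    relative depth is ≥ 1 + ``call_threshold`` and a loss when ≤ 1 −
    ``call_threshold``.
    """
    params = params or CnvParams()
    per_chrom: dict[str, tuple[float, float, bool, int, int]] = {}
    for chrom, w in window_means.groupby("chrom", sort=True):
        w = w.dropna(subset=["mean_depth"]).sort_values("start")
        mean, eff, smile, n_out = _effective_mean(w, params)
        per_chrom[chrom] = (mean, eff, smile, n_out, len(w))

    usable = {c: v for c, v in per_chrom.items() if v[4] >= params.min_windows}
    if not usable:
        raise ValueError("no chromosome has enough windows for a genome baseline")
    eff_means = np.array([v[1] for v in usable.values()])
    genome_mean = float(
        eff_means.mean() if params.genome_stat == "mean" else np.median(eff_means)
    )

    out = []
    for chrom, (mean, eff, smile, n_out, n_win) in per_chrom.items():
        rel = eff / genome_mean
        if n_win < params.min_windows:
            warnings.warn(f"chromosome {chrom} has {n_win} windows; call suppressed")
            call = "suppressed"
        elif rel >= 1.0 + params.call_threshold:
            call = "gain"
        elif rel <= 1.0 - params.call_threshold:
            call = "loss"
        else:
            call = "none"
        out.append(
            ChromosomeDepthSummary(
                chrom=chrom, sample=sample, mean_depth=mean, smile_flag=smile,
                effective_mean=eff, relative_depth=float(rel), call=call,
                magnitude=float(rel - 1.0), n_windows=n_win, n_outlier_windows=n_out,
            )
        )
    return out


@dataclass
class LocalCnvReport:
    chrom: str
    start: int
    end: int
    flank: int
    target_mean: float
    flank_mean: float
    ratio: float
    verdict: str  # changed / unchanged
    flank_truncated: bool


def local_cnv_ratio(
    track: DepthTrack,
    chrom: str,
    start: int,
    end: int,
    flank: int = 100_000,
    call_threshold: float = 0.25,
) -> LocalCnvReport:
    """Depth of a target interval relative to its flanking regions.

    Flanks of ``flank`` bp on each side exclude the target; flanks falling
    off the chromosome are truncated (recorded in ``flank_truncated``). The
    verdict is "changed" when the ratio leaves [1 − t, 1 + t] with the same
    ±25% convention as chromosome calls.
    """
    df = track.records[track.records["chrom"] == chrom]
    if df.empty:
        raise ValueError(f"no depth records for chromosome {chrom!r}")
    pos = df["pos"].to_numpy()
    depth = df["depth"].to_numpy(dtype=float)
    in_target = (pos >= start) & (pos <= end)
    left_lo, right_hi = start - flank, end + flank
    in_flank = ((pos >= left_lo) & (pos < start)) | ((pos > end) & (pos <= right_hi))
    truncated = left_lo < pos.min() or right_hi > pos.max()
    if not in_flank.any():
        raise ValueError("zero flank coverage around target interval")
    if not in_target.any():
        raise ValueError("no depth records inside target interval")
    target_mean = float(depth[in_target].mean())
    flank_mean = float(depth[in_flank].mean())
    ratio = target_mean / flank_mean
    verdict = (
        "changed"
        if (ratio >= 1.0 + call_threshold or ratio <= 1.0 - call_threshold)
        else "unchanged"
    )
    return LocalCnvReport(
        chrom=chrom, start=start, end=end, flank=flank,
        target_mean=target_mean, flank_mean=flank_mean, ratio=float(ratio),
        verdict=verdict, flank_truncated=bool(truncated),
    )


def summaries_to_frame(summaries: list[ChromosomeDepthSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
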