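"""Depth-based copy-number tracts and genome-size change.

Depth of coverage of subgenome-sorted reads, mapped on the haploid parental
reference, is summarized in non-overlapping windows (30 kb for tract
calling, 10 kb for genome-size change). Window medians are normalized by
the genome-wide median, quantized to a 0.5 grid of relative depth (so the
2:1 subgenome ratios of triploid lines land on clean levels), and runs of
equal level are merged into tracts. A tract's copy number is its level
times the subgenome's baseline copy count from ploidy metadata — median
normalization cancels whole-genome ploidy, which therefore must come from
metadata, not depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["depth_to_tracts", "locus_cn", "genome_size_change", "SizeChange"]


def _windowed_medians(depth: pd.DataFrame, window: int) -> pd.DataFrame:
    """Median depth per non-overlapping window; partial trailing windows kept."""
    rows = []
    for chrom, g in depth.groupby("chrom", sort=False):
        g = g.sort_values("start")
        mids = (g["start"].to_numpy() + g["end"].to_numpy()) // 2
        win = mids // window
        length = g["end"].to_numpy() - g["start"].to_numpy()
        for w in np.unique(win):
            sel = win == w
            rows.append(
                (
                    chrom,
                    int(w * window),
                    int(g["end"].to_numpy()[sel].max()),
                    float(np.median(g["depth"].to_numpy()[sel])),
                    int(length[sel].sum()),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "median", "span"])


def _quantize_half(r: np.ndarray) -> np.ndarray:
    """Round to the nearest multiple of 0.5, ties rounding half up."""
    return np.floor(r * 2.0 + 0.5) / 2.0


def depth_to_tracts(
    depth: pd.DataFrame,
    window: int = 30_000,
    baseline_copies: int = 1,
) -> pd.DataFrame:
    """Quantized relative-depth tracts from a per-window depth track.

    Parameters
    ----------
    depth : DataFrame with columns chrom, start, end, depth
        Input track at any resolution <= ``window``.
    window : int
        Aggregation window in bases (30 kb default).
    baseline_copies : int
        Haplotype copies corresponding to relative depth 1.0 (ploidy
        metadata for the subgenome).

    Returns
    -------
    DataFrame with columns chrom, start, end, level, copy_number; tracts
    tile each chromosome and adjacent tracts differ in level.
    """
    if depth.empty:
        raise ValueError("empty depth track")
    win = _windowed_medians(depth, window)
    genome_median = float(np.median(win["median"]))
    if genome_median <= 0:
        raise ValueError("genome-wide median depth is zero; cannot normalize")
    win["level"] = _quantize_half(win["median"].to_numpy() / genome_median)
    tracts = []
    for chrom, g in win.groupby("chrom", sort=False):
        g = g.sort_values("start").reset_index(drop=True)
        run_start = 0
        lv = g["level"].to_numpy()
        for i in range(1, len(g) + 1):
            if i == len(g) or lv[i] != lv[run_start]:
                tracts.append(
                    (
                        chrom,
                        int(g["start"].iloc[run_start]),
                        int(g["end"].iloc[i - 1]),
                        float(lv[run_start]),
                        float(lv[run_start]) * baseline_copies,
                    )
                )
                run_start = i
    return pd.DataFrame(
        tracts, columns=["chrom", "start", "end", "level", "copy_number"]
    )


def locus_cn(tracts: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Copy number of the tract containing the locus midpoint."""
    mid = (start + end) // 2
    sel = tracts[
        (tracts["chrom"] == chrom)
        & (tracts["start"] <= mid)
        & (tracts["end"] > mid)
    ]
    if sel.empty:
        raise KeyError(f"locus {chrom}:{start}-{end} outside any tract")
    return float(sel["copy_number"].iloc[0])


@dataclass(frozen=True)
class SizeChange:
    """Genome-size change of one subgenome relative to its haploid parent."""

    delta_mb: float
    bins_used: int
    excluded_bins: int


def genome_size_change(
    depth: pd.DataFrame, bin_size: int = 10_000
) -> SizeChange:
    """Depth-implied genome-size change in Mb.

    Each bin's median depth is normalized by the genome-wide median; bins
    strictly below the 1st or strictly above the 99th percentile of the
    normalized values are excluded as outliers; the remaining bins
    contribute ``(r - 1) * bin length``, summed and reported in Mb.
    Whole-genome ploidy changes normalize out (handled via ploidy
    metadata, not here).
    """
    bins = _windowed_medians(depth, bin_size)
    if len(bins) < 100:
        raise ValueError("need at least 100 bins for genome-size change")
    genome_median = float(np.median(bins["median"]))
    if genome_median <= 0:
        raise ValueError("genome-wide median depth is zero")
    r = bins["median"].to_numpy() / genome_median
    lo, hi = np.percentile(r, [1, 99])
    keep = (r >= lo) & (r <= hi)
    span = bins["span"].to_numpy()
    delta = float(np.sum((r[keep] - 1.0) * span[keep])) / 1e6
    return SizeChange(
        delta_mb=delta,
        bins_used=int(keep.sum()),
        excluded_bins=int((~keep).sum()),
    )
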