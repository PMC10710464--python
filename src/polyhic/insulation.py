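"""Sliding-window insulation scores and differential-insulation calling.

The insulation score of bin b is the log2 ratio of the mean balanced
signal in the w x w square spanning [b-w, b-1] x [b+1, b+w] (contacts
crossing b) to the chromosome-wide mean of such square means. More
negative = more insulating; local minima mark TAD boundaries.

Differential calling between conditions applies the thresholds used for
the two-condition comparison: a bin is eligible when at least one
condition scores below the `score_floor` (-0.2 by default, excluding
lowly insulated portions of the genome; an optional strict `exclude_above`
cutoff of -1 is exposed but off by default since it subsumes the floor),
and is called a gain (KO more insulating) or loss when |delta| meets the
`delta_threshold` (0.2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import GenomeBinning, Track
from .contact import ContactMatrix

__all__ = ["insulation_track", "call_differential_insulation",
           "merge_calls", "insulation_heatmap", "InsulationHeatmap"]

CATEGORIES = ("gain", "loss", "unchanged", "excluded")


def insulation_track(matrix: ContactMatrix, window: int = 250_000) -> Track:
    """Per-bin insulation score at the matrix resolution.

    `window` (bp) must be a multiple of the bin size. Scores are missing
    within one window of chromosome ends, on masked bins, and on
    chromosomes shorter than the window (skipped with a warning).
    """
    bn = matrix.binning
    if window % bn.binsize != 0 or window < bn.binsize:
        raise ValueError("window must be a positive multiple of the bin size")
    w = window // bn.binsize
    values = np.full(bn.n_bins, np.nan)
    for chrom in matrix.chroms:
        n = bn.chrom_nbins(chrom)
        if n < 2 * w + 1:
            warnings.warn(f"{chrom}: shorter than the {window} bp window; skipped")
            continue
        D = matrix.balanced_dense(chrom)
        finite = np.isfinite(D)
        Dz = np.where(finite, D, 0.0)
        # integral images with a zero row/col of padding
        I = np.zeros((n + 1, n + 1))
        I[1:, 1:] = Dz.cumsum(0).cumsum(1)
        C = np.zeros((n + 1, n + 1))
        C[1:, 1:] = finite.astype(float).cumsum(0).cumsum(1)

        def box(M, r0, r1, c0, c1):      # sum over rows [r0,r1), cols [c0,c1)
            return M[r1, c1] - M[r0, c1] - M[r1, c0] + M[r0, c0]

        b = np.arange(w, n - w)
        sums = box(I, b - w, b, b + 1, b + w + 1)
        cnts = box(C, b - w, b, b + 1, b + w + 1)
        masked = ~np.isfinite(matrix.weights[chrom])
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(cnts > 0, sums / cnts, np.nan)
        means[masked[b]] = np.nan
        chrom_mean = np.nanmean(means) if np.isfinite(means).any() else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.log2(means / chrom_mean)
        off = bn.chrom_offset(chrom)
        values[off + w:off + n - w] = scores
    return Track(bn, values, label=f"insulation_{window}")


def call_differential_insulation(track_wt: Track, track_ko: Track,
                                 delta_threshold: float = 0.2,
                                 score_floor: float = -0.2,
                                 exclude_above: float | None = None
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every bin as gain / loss / unchanged / excluded.

    delta = score_KO - score_WT. "gain" (KO more insulating) when
    delta <= -delta_threshold, "loss" when delta >= +delta_threshold.
    A bin is eligible when both scores are defined and
    min(score_WT, score_KO) < score_floor; if `exclude_above` is given
    (e.g. -1), bins with min score above it are additionally excluded.
    Swapping the two tracks exactly swaps gain and loss.

    Returns (per-bin calls, merged gain/loss regions).
    """
    if track_wt.binning != track_ko.binning:
        raise ValueError("tracks are on different binnings")
    bn = track_wt.binning
    swt, sko = track_wt.values, track_ko.values
    delta = sko - swt
    both = np.isfinite(swt) & np.isfinite(sko)
    lo = np.minimum(swt, sko)
    eligible = both & (lo < score_floor)
    if exclude_above is not None:
        eligible &= lo <= exclude_above
    category = np.full(bn.n_bins, "excluded", dtype=object)
    category[eligible] = "unchanged"
    category[eligible & (delta <= -delta_threshold)] = "gain"
    category[eligible & (delta >= delta_threshold)] = "loss"
    calls = bn.bins()
    calls["score_wt"] = swt
    calls["score_ko"] = sko
    calls["delta"] = delta
    calls["category"] = category
    if not eligible.any():
        warnings.warn("all bins excluded from differential insulation")
    return calls, merge_calls(calls)


def merge_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of adjacent same-category gain/loss bins into regions."""
    rows = []
    sel = calls[calls["category"].isin(["gain", "loss"])]
    for (chrom, cat), grp in sel.groupby(["chrom", "category"], sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        deltas = grp["delta"].to_numpy()
        run_start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or starts[i] != ends[i - 1]:
                rows.append((chrom, int(starts[run_start]), int(ends[i - 1]), cat,
                             i - run_start, float(deltas[run_start:i].mean())))
                run_start = i
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "category",
                                      "n_bins", "mean_delta"])
    return out.sort_values(["chrom", "start"], ignore_index=True)


@dataclass
class InsulationHeatmap:
    """Region x offset matrices of insulation scores, one per track."""

    offsets: np.ndarray          # bp relative to region midpoints
    matrices: dict               # label -> ndarray (n_regions x n_offsets)
    regions: pd.DataFrame        # row order matches the matrices


def insulation_heatmap(regions: pd.DataFrame, tracks: dict,
                       flank: int = 300_000) -> InsulationHeatmap:
    """Stack track values around region midpoints (rows sorted by the
    central score of the first track; NaN padding near chromosome ends)."""
    first = next(iter(tracks.values()))
    bn = first.binning
    if flank % bn.binsize != 0:
        raise ValueError("flank must be a multiple of the bin size")
    fb = flank // bn.binsize
    offsets = np.arange(-fb, fb + 1) * bn.binsize
    mats = {lab: np.full((len(regions), 2 * fb + 1), np.nan) for lab in tracks}
    for r, row in enumerate(regions.itertuples(index=False)):
        mid = (row.start + row.end) // 2
        cbin = bn.bin_index(row.chrom, min(mid, bn.chromsizes[row.chrom] - 1))
        off = bn.chrom_offset(row.chrom)
        n = bn.chrom_nbins(row.chrom)
        lo, hi = cbin - fb, cbin + fb + 1
        slo, shi = max(0, lo), min(n, hi)
        for lab, tr in tracks.items():
            mats[lab][r, slo - lo:(2 * fb + 1) - (hi - shi)] = \
                tr.values[off + slo:off + shi]
    lab0 = next(iter(tracks))
    order = np.argsort(mats[lab0][:, fb], kind="stable")
    return InsulationHeatmap(
        offsets, {lab: m[order] for lab, m in mats.items()},
        regions.iloc[order].reset_index(drop=True))
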