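"""Polycomb target-gene and loop classification, loop geometry, distance
analyses, and meta-profiles at anchors.

Gene classes follow the occupancy logic used for ESC Polycomb annotation:
a TSS with a non-methylated CpG island (BioCap peak within +/-3 kb) is an
NMI TSS; NMI TSSs bound by both RING1B and SUZ12 are "prc1prc2" targets,
by RING1B only "vprc1", by neither "nonpcg"; methylated, CpG-poor TSSs are
"other". A loop is a Polycomb (pcg) loop when both anchors carry RING1B,
and a prc1prc2 loop when both anchors additionally harbor a prc1prc2 TSS.

All interval predicates use 0-based half-open coordinates and >= 1 bp
overlap; they are vectorised with sorted-array searches and are checked
against brute-force oracles in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .binning import GenomeBinning, Track
from .compartments import CompartmentTrack

__all__ = [
    "GENE_CLASSES", "classify_tss", "classify_loops", "bifurcate_loops",
    "loop_geometry", "distance_to_nearest", "rank_sum_less", "meta_profile",
    "compartment_track_from_labels",
]

GENE_CLASSES = ("prc1prc2", "vprc1", "nonpcg", "other")
TSS_WINDOW = 3000


# -- interval index ----------------------------------------------------------

class _IntervalIndex:
    """Per-chromosome sorted intervals supporting overlap and distance
    queries in O(log n)."""

    def __init__(self, intervals: pd.DataFrame):
        if len(intervals) and (intervals["end"] <= intervals["start"]).any():
            raise ValueError("malformed interval with end <= start")
        self._by_chrom = {}
        for chrom, grp in intervals.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            self._by_chrom[chrom] = (starts, np.maximum.accumulate(ends), ends)

    def overlaps(self, chrom: str, q0, q1) -> np.ndarray:
        """Vectorised: does any interval intersect [q0, q1)?"""
        q0 = np.atleast_1d(np.asarray(q0, np.int64))
        q1 = np.atleast_1d(np.asarray(q1, np.int64))
        if chrom not in self._by_chrom:
            return np.zeros(len(q0), bool)
        starts, cummax_end, _ = self._by_chrom[chrom]
        i = np.searchsorted(starts, q1, side="left")  # intervals starting before q1
        hit = np.zeros(len(q0), bool)
        nz = i > 0
        hit[nz] = cummax_end[i[nz] - 1] > q0[nz]
        return hit

    def distance(self, chrom: str, pos) -> np.ndarray:
        """Distance from point(s) to the nearest interval (0 if inside,
        NaN if the chromosome holds no interval)."""
        pos = np.atleast_1d(np.asarray(pos, np.int64))
        if chrom not in self._by_chrom:
            return np.full(len(pos), np.nan)
        starts, cummax_end, _ = self._by_chrom[chrom]
        inside = self.overlaps(chrom, pos, pos + 1)
        i = np.searchsorted(starts, pos, side="right")
        d_right = np.where(i < len(starts), starts[np.minimum(i, len(starts) - 1)]
                           - pos, np.iinfo(np.int64).max)
        d_left = np.where(i > 0, pos - cummax_end[np.maximum(i - 1, 0)] + 1,
                          np.iinfo(np.int64).max)
        d = np.minimum(d_right, d_left).astype(float)
        d[inside] = 0.0
        return d


# -- gene classification -----------------------------------------------------

def classify_tss(genes: pd.DataFrame, biocap: pd.DataFrame,
                 ring1b: pd.DataFrame, suz12: pd.DataFrame,
                 window: int = TSS_WINDOW,
                 chromsizes: dict | None = None) -> pd.DataFrame:
    """Assign each gene one of the four classes (a partition of the genes).

    A peak "marks" a TSS when it overlaps [TSS - window, TSS + window).
    Returns a copy of `genes` with a `gene_class` column.
    """
    if chromsizes is not None:
        unknown = set(genes["chrom"]) - set(chromsizes)
        if unknown:
            raise ValueError(f"genes on unknown chromosomes: {sorted(unknown)}")
    idx_bio = _IntervalIndex(biocap)
    idx_r1b = _IntervalIndex(ring1b)
    idx_suz = _IntervalIndex(suz12)
    out = genes.copy().reset_index(drop=True)
    cls = np.full(len(out), "other", dtype=object)
    for chrom, grp in out.groupby("chrom", sort=False):
        tss = grp["tss"].to_numpy(np.int64)
        q0, q1 = np.maximum(tss - window, 0), tss + window
        nmi = idx_bio.overlaps(chrom, q0, q1)
        r1b = idx_r1b.overlaps(chrom, q0, q1)
        suz = idx_suz.overlaps(chrom, q0, q1)
        c = np.where(~nmi, "other",
                     np.where(r1b & suz, "prc1prc2",
                              np.where(r1b, "vprc1", "nonpcg")))
        cls[grp.index.to_numpy()] = c
    out["gene_class"] = cls
    return out


# -- loop classification -----------------------------------------------------

def _anchor_frames(loops: pd.DataFrame):
    a1 = loops[["chrom1", "start1", "end1"]].rename(
        columns={"chrom1": "chrom", "start1": "start", "end1": "end"})
    a2 = loops[["chrom2", "start2", "end2"]].rename(
        columns={"chrom2": "chrom", "start2": "start", "end2": "end"})
    for a in (a1, a2):
        if len(a) and (a["end"] <= a["start"]).any():
            raise ValueError("malformed anchor with end <= start")
    return a1, a2


def _anchor_has(index: _IntervalIndex, anchors: pd.DataFrame,
                pad: int = 0) -> np.ndarray:
    hit = np.zeros(len(anchors), bool)
    for chrom, grp in anchors.groupby("chrom", sort=False):
        hit[grp.index.to_numpy()] = index.overlaps(
            chrom, grp["start"].to_numpy() - pad, grp["end"].to_numpy() + pad)
    return hit


def classify_loops(loops: pd.DataFrame, ring1b: pd.DataFrame,
                   genes: pd.DataFrame, window: int = TSS_WINDOW,
                   require_both_anchors: bool = True) -> pd.DataFrame:
    """Label loops nonpcg / pcg / prc1prc2.

    pcg: RING1B peak overlapping both anchors (>= 1 bp; set
    `require_both_anchors=False` for a single-anchor rule). prc1prc2: pcg
    and a prc1prc2-class TSS within `window` of both anchors. `genes` must
    carry `gene_class` (from :func:`classify_tss`) and a `tss` column.
    """
    a1, a2 = _anchor_frames(loops)
    idx_r1b = _IntervalIndex(pd.concat([a1[:0], ring1b]))  # validates columns
    prc_tss = genes[genes["gene_class"] == "prc1prc2"]
    idx_tss = _IntervalIndex(pd.DataFrame({
        "chrom": prc_tss["chrom"],
        "start": prc_tss["tss"], "end": prc_tss["tss"] + 1}))
    r1 = _anchor_has(idx_r1b, a1.reset_index(drop=True))
    r2 = _anchor_has(idx_r1b, a2.reset_index(drop=True))
    pcg = (r1 & r2) if require_both_anchors else (r1 | r2)
    t1 = _anchor_has(idx_tss, a1.reset_index(drop=True), pad=window)
    t2 = _anchor_has(idx_tss, a2.reset_index(drop=True), pad=window)
    out = loops.copy().reset_index(drop=True)
    out["pcg_class"] = np.where(pcg & t1 & t2, "prc1prc2",
                                np.where(pcg, "pcg", "nonpcg"))
    return out


def bifurcate_loops(loops: pd.DataFrame, genes: pd.DataFrame,
                    window: int = TSS_WINDOW) -> pd.DataFrame:
    """Split prc1prc2 loops by expression response of their anchor genes.

    `genes` must carry `gene_class` and `de_status` (up/down/unchanged).
    A loop is "up" when at least one anchor harbors an upregulated
    prc1prc2 gene within `window`, "not_up" otherwise, and "na" when
    neither anchor contains any classified prc1prc2 gene (excluded from
    counts). Per-anchor side labels (side1/side2: up|unchanged) support
    side-split meta-profiles. Adding an upregulated gene to an anchor can
    only move a loop from not_up to up (monotonicity).
    """
    prc = genes[genes["gene_class"] == "prc1prc2"]
    up = prc[prc["de_status"] == "up"]

    def tss_index(df):
        return _IntervalIndex(pd.DataFrame(
            {"chrom": df["chrom"], "start": df["tss"], "end": df["tss"] + 1}))

    idx_any, idx_up = tss_index(prc), tss_index(up)
    a1, a2 = (a.reset_index(drop=True) for a in _anchor_frames(loops))
    any1 = _anchor_has(idx_any, a1, pad=window)
    any2 = _anchor_has(idx_any, a2, pad=window)
    up1 = _anchor_has(idx_up, a1, pad=window)
    up2 = _anchor_has(idx_up, a2, pad=window)
    out = loops.copy().reset_index(drop=True)
    is_prc = (out["pcg_class"] == "prc1prc2").to_numpy() \
        if "pcg_class" in out else np.ones(len(out), bool)
    out["side1"] = np.where(up1, "up", "unchanged")
    out["side2"] = np.where(up2, "up", "unchanged")
    bif = np.where(up1 | up2, "up", "not_up").astype(object)
    bif[~(any1 | any2)] = "na"
    bif[~is_prc] = "na"
    out["bifurcation"] = bif
    return out


# -- loop geometry -----------------------------------------------------------

def compartment_track_from_labels(binning: GenomeBinning,
                                  labels: dict) -> CompartmentTrack:
    """CompartmentTrack from per-chromosome 'A'/'B' label arrays (e.g. a
    planted truth), with a +/-1 eigenvector placeholder."""
    values = np.full(binning.n_bins, np.nan)
    labs = np.full(binning.n_bins, "", dtype="U1")
    for chrom, lab in labels.items():
        off = binning.chrom_offset(chrom)
        labs[off:off + len(lab)] = lab
        values[off:off + len(lab)] = np.where(lab == "A", 1.0, -1.0)
    return CompartmentTrack(Track(binning, values, label="E1"), labs)


def loop_geometry(loops: pd.DataFrame, tads: pd.DataFrame,
                  compartments: CompartmentTrack) -> pd.DataFrame:
    """Per-loop length (midpoint distance) and TADs traversed.

    A TAD is traversed when it lies strictly between the two anchor
    midpoints and its majority compartment label matches the loop's
    majority label over its span. Loops whose anchors sit in different
    compartments get the label covering more of the span and are flagged.
    """
    bn = compartments.binning

    def majority(chrom, lo, hi):
        labs = compartments.chrom_labels(chrom)
        b0 = min(lo // bn.binsize, len(labs) - 1)
        b1 = min(hi // bn.binsize, len(labs) - 1)
        seg = labs[b0:b1 + 1]
        na = (seg == "A").sum()
        nb = (seg == "B").sum()
        return "A" if na >= nb else "B"

    tad_lab = {}
    for t, tad in enumerate(tads.itertuples(index=False)):
        tad_lab[t] = majority(tad.chrom, tad.start, tad.end - 1)
    rows = []
    for lp in loops.itertuples(index=False):
        mid1 = (lp.start1 + lp.end1) // 2
        mid2 = (lp.start2 + lp.end2) // 2
        if mid2 < mid1:
            mid1, mid2 = mid2, mid1
        lab = majority(lp.chrom1, mid1, mid2 - 1)
        lab1 = majority(lp.chrom1, mid1, mid1)
        lab2 = majority(lp.chrom1, mid2, mid2)
        count = 0
        for t, tad in enumerate(tads.itertuples(index=False)):
            if (tad.chrom == lp.chrom1 and tad.start > mid1 and tad.end < mid2
                    and tad_lab[t] == lab):
                count += 1
        rows.append((mid2 - mid1, lab, count, lab1 != lab2))
    out = loops.copy().reset_index(drop=True)
    out[["length", "compartment", "tads_traversed", "anchors_span_compartments"]] = \
        pd.DataFrame(rows, columns=["length", "compartment", "tads_traversed",
                                    "anchors_span_compartments"])
    return out


def cumulative_lengths(geometry: pd.DataFrame, by: str = "pcg_class") -> dict:
    """Right-continuous empirical CDF of loop length per class."""
    out = {}
    for cls, grp in geometry.groupby(by, sort=False):
        x = np.sort(grp["length"].to_numpy())
        out[cls] = pd.DataFrame({"length": x,
                                 "cdf": np.arange(1, len(x) + 1) / len(x)})
    return out


# -- distances ---------------------------------------------------------------

def distance_to_nearest(queries: pd.DataFrame, targets: pd.DataFrame,
                        pos_col: str = "tss") -> pd.Series:
    """Distance (bp) from each query point to the nearest target region;
    0 inside a region, NaN when the chromosome has no target."""
    idx = _IntervalIndex(targets)
    out = np.full(len(queries), np.nan)
    q = queries.reset_index(drop=True)
    for chrom, grp in q.groupby("chrom", sort=False):
        out[grp.index.to_numpy()] = idx.distance(
            chrom, grp[pos_col].to_numpy(np.int64))
    return pd.Series(out, index=queries.index, name="distance")


def rank_sum_less(x, y) -> float:
    """One-sided Wilcoxon rank-sum p-value for the hypothesis that `x`
    tends to be smaller than `y`."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        return np.nan
    return float(stats.mannwhitneyu(x, y, alternative="less").pvalue)


# -- meta profiles -----------------------------------------------------------

def meta_profile(track: Track, intervals: pd.DataFrame, flank: int,
                 n_bins: int | None = None) -> pd.DataFrame:
    """Mean track signal around interval midpoints (strand-aware).

    Returns a DataFrame with offset (bp), mean, sem and n per offset bin.
    `n_bins` defaults to the number of track bins covering +/- flank.
    """
    if len(intervals) == 0:
        raise ValueError("empty interval set")
    bn = track.binning
    fb = flank // bn.binsize
    width = 2 * fb + 1 if n_bins is None else n_bins
    fb = width // 2
    rows = np.full((len(intervals), width), np.nan)
    for r, iv in enumerate(intervals.itertuples(index=False)):
        mid = (iv.start + iv.end) // 2
        cbin = bn.bin_index(iv.chrom, min(mid, bn.chromsizes[iv.chrom] - 1))
        off = bn.chrom_offset(iv.chrom)
        n = bn.chrom_nbins(iv.chrom)
        lo, hi = cbin - fb, cbin + fb + 1
        slo, shi = max(0, lo), min(n, hi)
        vals = np.full(width, np.nan)
        vals[slo - lo:width - (hi - shi)] = track.values[off + slo:off + shi]
        if getattr(iv, "strand", "+") == "-":
            vals = vals[::-1]
        rows[r] = vals
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(rows, axis=0)
        n_obs = np.isfinite(rows).sum(axis=0)
        sd = np.nanstd(rows, axis=0, ddof=1) if len(intervals) > 1 else \
            np.zeros(width)
    sem = np.where(n_obs > 0, sd / np.sqrt(np.maximum(n_obs, 1)), np.nan)
    return pd.DataFrame({"offset": (np.arange(width) - fb) * bn.binsize,
                         "mean": mean, "sem": sem, "n": n_obs})
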