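"""Aggregate (pileup) analyses: loop pileups, rescaled TAD pileups, and the
TAD-boundary-violation statistic.

Pileups average observed/expected submatrices over a set of genomic items,
so a value of 1 means "as expected at that distance". Central enrichment of
a loop pileup is the mean of the central 3x3 pixels over the mean of the
two off-loop corner blocks (toward and away from the diagonal on the
anchor1 < anchor2 side) — a documented convention, recomputable from the
stored submatrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import GenomeBinning
from .contact import ContactMatrix, oe_dense

__all__ = ["PileupResult", "loop_pileup", "tad_pileup",
           "tad_boundary_violation", "shuffle_loops", "central_enrichment"]


@dataclass
class PileupResult:
    """Mean O/E submatrix over aggregated items plus its enrichment."""

    matrix: np.ndarray           # n x n (odd n)
    n_items: int
    window: int                  # bp
    resolution: int              # bp
    enrichment: float
    n_skipped: int = 0


def central_enrichment(mat: np.ndarray) -> float:
    """Mean of the central block over the mean of the two off-loop corners.

    Center is 3x3 and corners 6x6 for the standard 21-bin window; both
    shrink proportionally for smaller windows.
    """
    n = mat.shape[0]
    c = 3 if n >= 7 else 1
    k = 6 if n >= 13 else max(1, n // 3)
    mid = n // 2
    center = mat[mid - c // 2: mid + c // 2 + 1, mid - c // 2: mid + c // 2 + 1]
    corner_near = mat[n - k:, :k]      # toward the diagonal
    corner_far = mat[:k, n - k:]       # away from the diagonal
    denom = np.nanmean(np.concatenate([corner_near.ravel(), corner_far.ravel()]))
    return float(np.nanmean(center) / denom)


def _anchor_bins(loops: pd.DataFrame, binning: GenomeBinning):
    """Yield (chrom, mid-bin1, mid-bin2) per intra-chromosomal loop."""
    for lp in loops.itertuples(index=False):
        if lp.chrom1 != lp.chrom2:
            continue
        m1 = binning.bin_index(lp.chrom1, (lp.start1 + lp.end1) // 2)
        m2 = binning.bin_index(lp.chrom2, (lp.start2 + lp.end2) // 2)
        if m1 > m2:
            m1, m2 = m2, m1
        yield lp.chrom1, m1, m2


def loop_pileup(matrix: ContactMatrix, loops: pd.DataFrame,
                window: int = 105_000) -> PileupResult:
    """Average O/E submatrices centred on loop anchor midpoints.

    `loops` is BEDPE-like (chrom1/start1/end1/chrom2/start2/end2). The
    window must span an odd number of bins (105 kb at 5 kb -> 21 x 21).
    Loops whose window does not fit inside the chromosome are skipped;
    zero usable loops is an error. The result is invariant to loop order.
    """
    bn = matrix.binning
    nwin = window // bn.binsize
    if nwin % 2 == 0 or nwin < 1:
        raise ValueError(f"window/resolution must be odd, got {nwin}")
    half = nwin // 2
    acc = np.zeros((nwin, nwin))
    cnt = np.zeros((nwin, nwin))
    used = skipped = 0
    oe_cache = {}
    for chrom, m1, m2 in _anchor_bins(loops, bn):
        n = bn.chrom_nbins(chrom)
        if m1 - half < 0 or m2 + half >= n:
            skipped += 1
            continue
        if chrom not in oe_cache:
            oe_cache[chrom] = oe_dense(matrix, chrom)
        sub = oe_cache[chrom][m1 - half:m1 + half + 1, m2 - half:m2 + half + 1]
        ok = np.isfinite(sub)
        acc[ok] += sub[ok]
        cnt += ok
        used += 1
    if used == 0:
        raise ValueError("no usable loops for pileup")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    return PileupResult(mean, used, window, bn.binsize,
                        central_enrichment(mean), n_skipped=skipped)


def shuffle_loops(loops: pd.DataFrame, binning: GenomeBinning,
                  seed: int = 0) -> pd.DataFrame:
    """Distance-matched shuffled anchors (the pileup null): each loop keeps
    its chromosome and anchor separation but gets a random position."""
    rng = np.random.default_rng(seed)
    rows = []
    bs = binning.binsize
    for chrom, m1, m2 in _anchor_bins(loops, binning):
        n = binning.chrom_nbins(chrom)
        span = m2 - m1
        if span >= n:
            continue
        a1 = int(rng.integers(0, n - span))
        rows.append((chrom, a1 * bs, (a1 + 1) * bs,
                     chrom, (a1 + span) * bs, (a1 + span + 1) * bs))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                       "chrom2", "start2", "end2"])


def tad_pileup(matrix: ContactMatrix, tads: pd.DataFrame,
               rescale_bins: int = 40, min_bins: int = 10) -> PileupResult:
    """Average O/E over TADs rescaled to a common grid.

    Each TAD block plus 50% flanks on both sides is linearly rescaled to a
    `rescale_bins` x `rescale_bins` grid (the TAD occupies the central
    half) and averaged. TADs shorter than `min_bins` bins, or whose flanked
    window leaves the chromosome, are skipped and counted. Enrichment is
    the mean over the central (TAD) block divided by the mean of the
    flank-x-flank corner crossing the domain.
    """
    bn = matrix.binning
    m = rescale_bins
    acc = np.zeros((m, m))
    cnt = np.zeros((m, m))
    used = skipped = 0
    oe_cache = {}
    for tad in tads.itertuples(index=False):
        s = bn.bin_index(tad.chrom, tad.start)
        e = bn.bin_index(tad.chrom, tad.end - 1) + 1
        L = e - s
        n = bn.chrom_nbins(tad.chrom)
        f = L // 2
        if L < min_bins or s - f < 0 or e + f > n:
            skipped += 1
            continue
        if tad.chrom not in oe_cache:
            oe_cache[tad.chrom] = oe_dense(matrix, tad.chrom)
        block = oe_cache[tad.chrom][s - f:e + f, s - f:e + f]
        res = _rescale(block, m)
        ok = np.isfinite(res)
        acc[ok] += res[ok]
        cnt += ok
        used += 1
    if used == 0:
        raise ValueError("no usable TADs for pileup")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    q = m // 4
    within = np.nanmean(mean[q:m - q, q:m - q])
    cross = np.nanmean(mean[:q, m - q:]) if q else np.nan
    return PileupResult(mean, used, window=0, resolution=bn.binsize,
                        enrichment=float(within / cross), n_skipped=skipped)


def _rescale(block: np.ndarray, m: int) -> np.ndarray:
    """Block-mean resample of a square matrix to m x m (identity when the
    sizes already match)."""
    src = block.shape[0]
    if src == m:
        return block
    edges = np.linspace(0, src, m + 1)
    out = np.empty((m, m))
    for p in range(m):
        r0, r1 = int(np.floor(edges[p])), max(int(np.floor(edges[p])) + 1,
                                              int(np.ceil(edges[p + 1])))
        for q in range(m):
            c0, c1 = int(np.floor(edges[q])), max(int(np.floor(edges[q])) + 1,
                                                  int(np.ceil(edges[q + 1])))
            out[p, q] = np.nanmean(block[r0:r1, c0:c1])
    return out


def tad_boundary_violation(matrix: ContactMatrix, tads: pd.DataFrame,
                           max_n: int = 4) -> dict:
    """Mean O/E between TAD pairs at separation n (0 = intra-TAD).

    For each n, pixels pooled over all pairs (TAD t, TAD t+n) on every
    chromosome; chromosomes with fewer than n+1 TADs contribute only the
    feasible separations. The KO - WT difference of these values is the
    boundary-violation profile.
    """
    bn = matrix.binning
    sums = {n: 0.0 for n in range(max_n + 1)}
    cnts = {n: 0 for n in range(max_n + 1)}
    for chrom, grp in tads.groupby("chrom", sort=False):
        if chrom not in matrix.chroms:
            continue
        grp = grp.sort_values("start")
        spans = [(bn.bin_index(chrom, r.start),
                  bn.bin_index(chrom, r.end - 1) + 1)
                 for r in grp.itertuples(index=False)]
        oe = oe_dense(matrix, chrom)
        for n in range(max_n + 1):
            for t in range(len(spans) - n):
                (s1, e1), (s2, e2) = spans[t], spans[t + n]
                block = oe[s1:e1, s2:e2]
                if n == 0:
                    block = block[np.triu_indices_from(block, k=1)]
                ok = np.isfinite(block)
                sums[n] += np.asarray(block)[ok].sum()
                cnts[n] += int(ok.sum())
    return {n: (sums[n] / cnts[n] if cnts[n] else np.nan)
            for n in range(max_n + 1)}
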