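"""Relative contact probability (RCP) as a function of genomic distance.

RCP is computed on raw (unbalanced) counts with per-pair normalisation —
each log-spaced distance bin reports the mean contact frequency per bin
pair, aggregated over chromosomes, and the curve is normalised to sum to
one over the analysed range. The between-condition comparison reports
log2(KO/WT) of the summed probability over named distance ranges; the
defaults (50-500 kb, 500 kb-5 Mb, >5 Mb) separate the TAD-scale,
extrusion-scale and compartment-scale regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactMatrix

__all__ = ["RCPCurve", "rcp_curve", "rcp_compare", "rcp_slope", "DEFAULT_RANGES"]

DEFAULT_RANGES = ((50_000, 500_000), (500_000, 5_000_000), (5_000_000, np.inf))


@dataclass
class RCPCurve:
    """Normalised contact probability per log-spaced distance bin."""

    edges: np.ndarray           # bp, length n+1
    prob: np.ndarray            # length n, sums to 1 over the range
    empty: np.ndarray           # bool, True where no pair was observed
    label: str = ""

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])


def rcp_curve(matrix: ContactMatrix, min_dist: int = 50_000,
              max_dist: int = 20_000_000, bins_per_decade: int = 10,
              label: str = "") -> RCPCurve:
    """Distance-binned mean per-pair contact frequency, normalised to 1."""
    bs = matrix.binning.binsize
    if not max_dist > min_dist >= bs:
        raise ValueError("need max_dist > min_dist >= bin size")
    n_edges = int(np.ceil(np.log10(max_dist / min_dist) * bins_per_decade)) + 1
    edges = np.logspace(np.log10(min_dist), np.log10(max_dist), n_edges)
    sums = np.zeros(len(edges) - 1)
    npairs = np.zeros(len(edges) - 1)
    for chrom in matrix.chroms:
        n = matrix.binning.chrom_nbins(chrom)
        coo = matrix.counts[chrom].tocoo()
        d_bp = (coo.col - coo.row).astype(float) * bs
        which = np.digitize(d_bp, edges) - 1
        ok = (which >= 0) & (which < len(sums)) & (d_bp >= min_dist)
        np.add.at(sums, which[ok], coo.data[ok])
        s = np.arange(1, n) * bs
        wb = np.digitize(s.astype(float), edges) - 1
        okb = (wb >= 0) & (wb < len(sums)) & (s >= min_dist)
        np.add.at(npairs, wb[okb], (n - np.arange(1, n))[okb])
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(npairs > 0, sums / npairs, 0.0)
    total = freq.sum()
    prob = freq / total if total > 0 else freq
    return RCPCurve(edges, prob, empty=npairs == 0, label=label)


def rcp_compare(curve_wt: RCPCurve, curve_ko: RCPCurve,
                ranges=DEFAULT_RANGES) -> dict:
    """Per-range log2(KO/WT) of the summed relative contact probability."""
    if not np.array_equal(curve_wt.edges, curve_ko.edges):
        raise ValueError("curves have mismatched distance-bin edges")
    centers = curve_wt.centers
    out = {}
    for lo, hi in ranges:
        sel = (centers >= lo) & (centers < hi)
        a, b = curve_wt.prob[sel].sum(), curve_ko.prob[sel].sum()
        name = f"{_fmt(lo)}-{_fmt(hi)}"
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = float(np.log2(b / a)) if a > 0 and b > 0 else np.nan
    return out


def rcp_slope(curve: RCPCurve, lo: float = 100_000, hi: float = 5_000_000) -> float:
    """Least-squares slope of log10(RCP) vs log10(distance) over [lo, hi)."""
    centers = curve.centers
    sel = (centers >= lo) & (centers < hi) & (curve.prob > 0)
    if sel.sum() < 2:
        raise ValueError("fewer than two usable distance bins for the slope fit")
    x, y = np.log10(centers[sel]), np.log10(curve.prob[sel])
    return float(np.polyfit(x, y, 1)[0])


def _fmt(x) -> str:
    if not np.isfinite(x):
        return "inf"
    if x >= 1e6:
        return f"{x/1e6:g}Mb"
    return f"{x/1e3:g}kb"
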