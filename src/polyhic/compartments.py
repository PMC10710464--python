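"""A/B compartment assignment and compartment strength.

Compartments are assigned per chromosome from the leading eigenvector of
the Pearson correlation matrix of the observed/expected map, with the
global sign fixed so the eigenvector correlates positively with an
orientation track (active-mark coverage, GC content, or planted labels);
positive values are called "A". Compartment strength contrasts long-range
within-compartment (A-A, B-B) against between-compartment (A-B) contacts
among the strongest-eigenvector bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import GenomeBinning, Track
from .contact import ContactMatrix, oe_dense

__all__ = ["CompartmentTrack", "eigenvector_compartments", "compartment_strength"]

MIN_BINS = 10


@dataclass
class CompartmentTrack:
    """Eigenvector values plus A/B labels on a (coarse) binning."""

    track: Track
    labels: np.ndarray          # 'A'/'B'/'' per bin ('' = undefined)

    @property
    def binning(self) -> GenomeBinning:
        return self.track.binning

    def chrom_labels(self, chrom: str) -> np.ndarray:
        off = self.binning.chrom_offset(chrom)
        return self.labels[off:off + self.binning.chrom_nbins(chrom)]


def eigenvector_compartments(matrix: ContactMatrix,
                             orientation: Track) -> CompartmentTrack:
    """First eigenvector of the per-chromosome O/E correlation matrix.

    The orientation track must live on the same binning; the eigenvector
    sign is flipped, per chromosome, so its correlation with the orientation
    track is positive, making labels invariant to the arbitrary sign of an
    eigendecomposition. Chromosomes with fewer than ten unmasked bins are
    skipped with a warning.
    """
    bn = matrix.binning
    if orientation.binning != bn:
        raise ValueError("orientation track is on a different binning")
    values = np.full(bn.n_bins, np.nan)
    labels = np.full(bn.n_bins, "", dtype="U1")
    for chrom in matrix.chroms:
        off = bn.chrom_offset(chrom)
        n = bn.chrom_nbins(chrom)
        oe = oe_dense(matrix, chrom)
        good = np.isfinite(oe).sum(axis=1) > 1
        if good.sum() < MIN_BINS:
            warnings.warn(f"{chrom}: fewer than {MIN_BINS} unmasked bins; skipped")
            continue
        sub = oe[np.ix_(good, good)]
        sub = np.where(np.isfinite(sub), sub, np.nanmean(sub))
        corr = np.corrcoef(sub)
        corr = np.where(np.isfinite(corr), corr, 0.0)
        evals, evecs = np.linalg.eigh(corr)
        ev = evecs[:, -1]
        ori = orientation.values[off:off + n][good]
        m = np.isfinite(ori)
        if m.sum() >= 2 and np.nanstd(ori[m]) > 0 and np.std(ev[m]) > 0:
            if np.corrcoef(ev[m], ori[m])[0, 1] < 0:
                ev = -ev
        chrom_vals = np.full(n, np.nan)
        chrom_vals[good] = ev
        values[off:off + n] = chrom_vals
        lab = np.full(n, "", dtype="U1")
        lab[good] = np.where(ev > 0, "A", "B")
        labels[off:off + n] = lab
    return CompartmentTrack(Track(bn, values, label="E1"), labels)


def compartment_strength(matrix: ContactMatrix, compartments: CompartmentTrack,
                         quantile: float = 0.2, min_dist: float = 2e6) -> dict:
    """log2( (mean AA * mean BB) / mean AB^2 ) among top-quantile bins.

    Only pixel pairs farther apart than `min_dist` contribute. "Top
    quantile" selects, per chromosome, the fraction `quantile` of A bins
    with the most positive eigenvector and of B bins with the most
    negative. Returns chrom -> strength plus a "genome" unweighted mean;
    chromosomes with an empty class are reported as NaN with a warning.
    """
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must lie in (0, 0.5]")
    bn = matrix.binning
    out = {}
    min_bins = int(min_dist / bn.binsize)
    for chrom in matrix.chroms:
        off = bn.chrom_offset(chrom)
        n = bn.chrom_nbins(chrom)
        ev = compartments.track.values[off:off + n]
        lab = compartments.chrom_labels(chrom)
        a_idx = np.flatnonzero((lab == "A") & np.isfinite(ev))
        b_idx = np.flatnonzero((lab == "B") & np.isfinite(ev))
        if a_idx.size == 0 or b_idx.size == 0:
            warnings.warn(f"{chrom}: empty compartment class; strength undefined")
            out[chrom] = np.nan
            continue
        ka = max(1, int(np.ceil(quantile * a_idx.size)))
        kb = max(1, int(np.ceil(quantile * b_idx.size)))
        top_a = a_idx[np.argsort(ev[a_idx])[-ka:]]
        top_b = b_idx[np.argsort(ev[b_idx])[:kb]]
        oe = oe_dense(matrix, chrom)
        dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        far = dist > min_bins

        def mean_pairs(rows, cols):
            blk = oe[np.ix_(rows, cols)]
            msk = far[np.ix_(rows, cols)] & np.isfinite(blk)
            return blk[msk].mean() if msk.any() else np.nan

        aa = mean_pairs(top_a, top_a)
        bb = mean_pairs(top_b, top_b)
        ab = mean_pairs(top_a, top_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[chrom] = float(np.log2(aa * bb / ab ** 2))
    vals = [v for v in out.values() if np.isfinite(v)]
    out["genome"] = float(np.mean(vals)) if vals else np.nan
    return out
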