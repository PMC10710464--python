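"""Genome binning: fixed-width tiling of chromosomes into half-open bins.

All coordinates in the package are 0-based, half-open. A bin is identified
by its (chrom, start) pair; bins tile each chromosome without gaps, and the
last bin of a chromosome may be short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeBinning", "Track"]


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width binning of a genome.

    Parameters
    ----------
    chromsizes
        Mapping of chromosome name -> length in bp. Iteration order defines
        the global bin order.
    binsize
        Bin width in bp.
    """

    chromsizes: dict  # chrom -> length (bp)
    binsize: int

    def __post_init__(self):
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")
        for chrom, length in self.chromsizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    # -- sizes ---------------------------------------------------------------

    @property
    def chroms(self) -> list:
        return list(self.chromsizes)

    def chrom_nbins(self, chrom: str) -> int:
        return -(-self.chromsizes[chrom] // self.binsize)  # ceil div

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_nbins(c) for c in self.chromsizes)

    def chrom_offset(self, chrom: str) -> int:
        """Global index of the first bin of `chrom`."""
        off = 0
        for c in self.chromsizes:
            if c == chrom:
                return off
            off += self.chrom_nbins(c)
        raise KeyError(f"unknown chromosome {chrom!r}")

    # -- coordinate <-> bin --------------------------------------------------

    def bin_index(self, chrom: str, pos: int) -> int:
        """Within-chromosome bin index containing position `pos`."""
        if not 0 <= pos < self.chromsizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} "
                             f"(length {self.chromsizes[chrom]})")
        return pos // self.binsize

    def bin_start(self, chrom: str, idx: int) -> int:
        n = self.chrom_nbins(chrom)
        if not 0 <= idx < n:
            raise ValueError(f"bin index {idx} outside {chrom} ({n} bins)")
        return idx * self.binsize

    def bins(self) -> pd.DataFrame:
        """Full bin table as a DataFrame with chrom/start/end columns."""
        rows = []
        for chrom, length in self.chromsizes.items():
            starts = np.arange(0, length, self.binsize)
            ends = np.minimum(starts + self.binsize, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def coarsen(self, factor: int) -> "GenomeBinning":
        """New binning with `factor`-times larger bins on the same genome."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return GenomeBinning(dict(self.chromsizes), self.binsize * factor)

    def __eq__(self, other):
        return (isinstance(other, GenomeBinning)
                and self.binsize == other.binsize
                and self.chromsizes == other.chromsizes)

    def __hash__(self):
        return hash((tuple(self.chromsizes.items()), self.binsize))


@dataclass
class Track:
    """One scalar per genomic bin (NaN where undefined), e.g. an insulation
    score, a compartment eigenvector, or a virtual-4C profile."""

    binning: GenomeBinning
    values: np.ndarray  # length binning.n_bins, float, NaN = missing
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.binning.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != number of bins "
                f"({self.binning.n_bins})")

    def chrom_values(self, chrom: str) -> np.ndarray:
        """View of the values for one chromosome."""
        off = self.binning.chrom_offset(chrom)
        return self.values[off:off + self.binning.chrom_nbins(chrom)]

    def to_frame(self) -> pd.DataFrame:
        df = self.binning.bins()
        df[self.label or "value"] = self.values
        return df

    def write_bedgraph(self, path) -> None:
        df = self.to_frame().dropna()
        df.to_csv(path, sep="\t", header=False, index=False)
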