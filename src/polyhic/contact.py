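"""Sparse cis contact matrices: I/O, iterative-correction balancing,
observed/expected, virtual 4C and differential matrices.

Storage is per chromosome, upper triangle canonical (row <= col). Balancing
weights are per-bin multipliers; masked (filtered) bins carry NaN weights and
propagate as missing through every downstream statistic — they never
contribute zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .binning import GenomeBinning, Track

__all__ = [
    "ContactMatrix", "BalanceError", "ice_balance", "expected_by_distance",
    "oe_dense", "virtual_4c", "differential_matrix", "coarsen",
    "read_contacts", "write_contacts",
]


class BalanceError(RuntimeError):
    """Iterative correction failed to converge; carries the last marginal
    coefficient of variation per chromosome."""

    def __init__(self, msg, last_cv=None):
        super().__init__(msg)
        self.last_cv = last_cv


@dataclass
class ContactMatrix:
    """Binned cis contact counts for one genome.

    Attributes
    ----------
    binning
        The shared :class:`GenomeBinning`.
    counts
        chrom -> upper-triangular ``scipy.sparse`` matrix of raw counts.
    weights
        chrom -> per-bin balancing weight vector (NaN on masked bins), or
        None before balancing.
    """

    binning: GenomeBinning
    counts: dict
    weights: dict | None = None
    _expected_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for chrom in self.counts:
            n = self.binning.chrom_nbins(chrom)
            m = sp.triu(sp.csr_matrix(self.counts[chrom]), k=0).tocsr() \
                .astype(np.float64)
            if m.shape != (n, n):
                raise ValueError(f"{chrom}: matrix shape {m.shape} != ({n},{n})")
            if m.nnz and m.data.min() < 0:
                raise ValueError(f"{chrom}: negative counts")
            self.counts[chrom] = m

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_dense(cls, binning: GenomeBinning, dense: dict) -> "ContactMatrix":
        """Build from symmetric dense arrays (used widely in tests)."""
        return cls(binning, {c: sp.csr_matrix(np.triu(np.asarray(d, float)))
                             for c, d in dense.items()})

    @classmethod
    def empty(cls, binning: GenomeBinning) -> "ContactMatrix":
        return cls(binning, {c: sp.csr_matrix((binning.chrom_nbins(c),) * 2)
                             for c in binning.chroms})

    # -- basic access --------------------------------------------------------

    @property
    def chroms(self) -> list:
        return list(self.counts)

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def total(self) -> float:
        """Total cis counts (upper triangle, diagonal once)."""
        return float(sum(m.sum() for m in self.counts.values()))

    def sym(self, chrom: str) -> sp.csr_matrix:
        """Symmetric sparse counts for one chromosome."""
        u = self.counts[chrom]
        d = sp.diags(u.diagonal())
        return (u + u.T - d).tocsr()

    def dense(self, chrom: str) -> np.ndarray:
        return np.asarray(self.sym(chrom).todense(), dtype=float)

    def balanced_dense(self, chrom: str) -> np.ndarray:
        """Dense symmetric balanced matrix; NaN rows/cols on masked bins."""
        self._require_weights()
        w = self.weights[chrom]
        m = self.dense(chrom) * np.outer(w, w)
        return m

    def mask(self, chrom: str) -> np.ndarray:
        """Boolean array, True where the bin is masked (unusable)."""
        self._require_weights()
        return ~np.isfinite(self.weights[chrom])

    def _require_weights(self):
        if self.weights is None:
            raise ValueError("matrix is not balanced; run ice_balance first")

    def pixels(self) -> pd.DataFrame:
        """Canonical pixel table: chrom, bin1, bin2 (bin indices), count."""
        frames = []
        for chrom, m in self.counts.items():
            coo = m.tocoo()
            order = np.lexsort((coo.col, coo.row))
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "bin1": coo.row[order], "bin2": coo.col[order],
                "count": coo.data[order]}))
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "bin1", "bin2", "count"])


# -- I/O (COO text dialect: chrom, bin1_start, bin2_start, count) ------------

def write_contacts(matrix: ContactMatrix, path) -> None:
    """Write the canonical upper-triangle COO text representation."""
    px = matrix.pixels()
    binsize = matrix.binning.binsize
    out = pd.DataFrame({
        "chrom": px["chrom"],
        "bin1_start": px["bin1"] * binsize,
        "bin2_start": px["bin2"] * binsize,
        "count": px["count"].astype(np.int64)})
    out.to_csv(path, sep="\t", index=False)


def read_contacts(path, binning: GenomeBinning) -> ContactMatrix:
    """Read a COO text contact file onto `binning`.

    Input may present pixels in either triangle; storage is canonicalised to
    the upper triangle. Duplicate pixels are summed with a warning; off-grid
    coordinates or unknown chromosomes raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "bin1_start", "bin2_start", "count"],
                     header=0 if _has_header(path) else None)
    per_chrom = {c: [] for c in binning.chroms}
    binsize = binning.binsize
    for line, row in enumerate(df.itertuples(index=False), start=2):
        if row.chrom not in binning.chromsizes:
            raise ValueError(f"{path}, line {line}: unknown chromosome {row.chrom!r}")
        for pos in (row.bin1_start, row.bin2_start):
            if pos % binsize != 0 or not 0 <= pos < binning.chromsizes[row.chrom]:
                raise ValueError(f"{path}, line {line}: coordinate {pos} is "
                                 f"off the {binsize} bp grid of {row.chrom}")
    mats = {}
    for chrom in binning.chroms:
        sub = df[df["chrom"] == chrom]
        n = binning.chrom_nbins(chrom)
        r = (sub["bin1_start"] // binsize).to_numpy(np.int64)
        c = (sub["bin2_start"] // binsize).to_numpy(np.int64)
        lo, hi = np.minimum(r, c), np.maximum(r, c)
        m = sp.coo_matrix((sub["count"].to_numpy(float), (lo, hi)), shape=(n, n))
        if len(lo) and len(np.unique(lo * n + hi)) < len(lo):
            warnings.warn(f"{path}: duplicate pixels on {chrom} were summed")
        mats[chrom] = m.tocsr()  # duplicate entries are summed by conversion
    return ContactMatrix(binning, mats)


def _has_header(path) -> bool:
    with open(path) as fh:
        first = fh.readline().split("\t")
    return len(first) >= 2 and not first[1].strip().lstrip("-").isdigit()


# -- balancing ---------------------------------------------------------------

def ice_balance(matrix: ContactMatrix, max_iter: int = 300, tol: float = 1e-5,
                mad_max: float = 5.0) -> dict:
    """Iterative correction (ICE) per chromosome, in place.

    Bins with zero coverage, or whose log10 marginal falls more than
    `mad_max` robust standard deviations below the chromosome median, are
    masked (weight NaN). Iteration stops when the coefficient of variation
    of the balanced marginals over unmasked bins drops below `tol`.

    Weights are scaled so the balanced marginals converge to 1, which makes
    balancing scale-invariant: scaling all counts by c rescales weights by
    c**-0.5 and leaves every O/E quantity unchanged.

    Returns chrom -> dict(n_iter, cv) diagnostics; raises
    :class:`BalanceError` on non-convergence.
    """
    if matrix.total() == 0:
        raise ValueError("cannot balance an empty matrix")
    weights, info = {}, {}
    for chrom in matrix.chroms:
        S = matrix.sym(chrom).astype(float)
        n = S.shape[0]
        marg = np.asarray(S.sum(axis=1)).ravel()
        masked = marg <= 0
        if mad_max is not None and (~masked).sum() > 1:
            logm = np.log10(marg[~masked])
            med = np.median(logm)
            mad = np.median(np.abs(logm - med)) * 1.4826
            if mad > 0:
                z = (logm - med) / mad
                low = np.zeros(n, bool)
                low[~masked] = z < -mad_max
                masked |= low
        b = np.ones(n)
        b[masked] = 0.0
        cv = np.inf
        converged = False
        for it in range(max_iter + 1):
            s = b * (S @ b)
            sm = s[~masked]
            if sm.size == 0:
                break
            mean = sm.mean()
            cv = float(sm.std() / mean) if mean > 0 else np.inf
            if cv < tol:
                converged = True
                break
            if it == max_iter:
                break
            b[~masked] /= s[~masked] / mean
        if not converged and (~masked).sum() > 1:
            raise BalanceError(
                f"{chrom}: ICE did not converge in {max_iter} iterations "
                f"(marginal CV {cv:.3g})", last_cv=cv)
        # scale so balanced marginals ~= 1
        s = b * (S @ b)
        mean = s[~masked].mean() if (~masked).any() else 1.0
        if mean > 0:
            b /= np.sqrt(mean)
        w = b.astype(float)
        w[masked] = np.nan
        weights[chrom] = w
        info[chrom] = {"n_iter": it, "cv": cv, "n_masked": int(masked.sum())}
    matrix.weights = weights
    matrix._expected_cache.clear()
    return info


# -- observed / expected -----------------------------------------------------

def expected_by_distance(matrix: ContactMatrix, chrom: str) -> np.ndarray:
    """Mean balanced signal per bin-distance s over unmasked pairs.

    Entry s is the average (including zero pixels) of w_i*w_j*x_{i,i+s} over
    all unmasked pairs at that separation; NaN where no unmasked pair exists.
    """
    matrix._require_weights()
    if chrom in matrix._expected_cache:
        return matrix._expected_cache[chrom]
    w = matrix.weights[chrom]
    valid = np.isfinite(w)
    n = len(w)
    coo = matrix.counts[chrom].tocoo()
    bal = w[coo.row] * w[coo.col] * coo.data
    ok = np.isfinite(bal)
    d = coo.col[ok] - coo.row[ok]
    sums = np.bincount(d, weights=bal[ok], minlength=n)
    npairs = np.empty(n)
    npairs[0] = valid.sum()
    v = valid.astype(np.float64)
    for s in range(1, n):
        npairs[s] = np.dot(v[:-s], v[s:])
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.where(npairs > 0, sums / npairs, np.nan)
    matrix._expected_cache[chrom] = exp
    return exp


def oe_dense(matrix: ContactMatrix, chrom: str,
             rows: slice | None = None, cols: slice | None = None) -> np.ndarray:
    """Dense observed/expected submatrix (whole chromosome by default).

    NaN on masked bins and at distances whose expected value is undefined.
    """
    matrix._require_weights()
    exp = expected_by_distance(matrix, chrom)
    n = len(exp)
    rows = rows if rows is not None else slice(0, n)
    cols = cols if cols is not None else slice(0, n)
    ri = np.arange(*rows.indices(n))
    ci = np.arange(*cols.indices(n))
    bal = matrix.balanced_dense(chrom)[np.ix_(ri, ci)]
    dist = np.abs(ci[None, :] - ri[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        return bal / exp[dist]


def virtual_4c(matrix: ContactMatrix, chrom: str, start: int, end: int,
               flank: int) -> Track:
    """One-dimensional contact profile from a viewpoint interval.

    The value at bin j is the mean balanced contact between the viewpoint
    bin(s) and j, restricted to +/- `flank` bp around the viewpoint; it
    equals the corresponding balanced matrix row(s) exactly.
    """
    matrix._require_weights()
    bn = matrix.binning
    b0 = bn.bin_index(chrom, start)
    b1 = bn.bin_index(chrom, max(start, end - 1))
    vp = np.arange(b0, b1 + 1)
    unmasked = vp[~matrix.mask(chrom)[vp]]
    if unmasked.size == 0:
        raise ValueError(f"viewpoint {chrom}:{start}-{end} covers only masked bins")
    n = bn.chrom_nbins(chrom)
    fb = flank // bn.binsize
    lo, hi = max(0, b0 - fb), min(n, b1 + 1 + fb)
    bal = matrix.balanced_dense(chrom)
    prof = bal[unmasked, lo:hi].mean(axis=0)
    values = np.full(bn.n_bins, np.nan)
    off = bn.chrom_offset(chrom)
    values[off + lo:off + hi] = prof
    return Track(bn, values, label=f"v4c_{chrom}:{start}-{end}")


def differential_matrix(matrix_a: ContactMatrix, matrix_b: ContactMatrix,
                        chrom: str, start: int | None = None,
                        end: int | None = None) -> np.ndarray:
    """Signed per-pixel O/E difference (b - a) over a region.

    Antisymmetric under swapping the inputs; NaN where either side is
    missing.
    """
    if matrix_a.binning != matrix_b.binning:
        raise ValueError("contact matrices are on different binnings")
    bn = matrix_a.binning
    n = bn.chrom_nbins(chrom)
    lo = 0 if start is None else bn.bin_index(chrom, start)
    hi = n if end is None else bn.bin_index(chrom, end - 1) + 1
    reg = slice(lo, hi)
    return oe_dense(matrix_b, chrom, reg, reg) - oe_dense(matrix_a, chrom, reg, reg)


# -- resolution change -------------------------------------------------------

def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum counts into `factor`-times larger bins (weights are dropped;
    re-balance at the new resolution)."""
    bn2 = matrix.binning.coarsen(factor)
    mats = {}
    for chrom, m in matrix.counts.items():
        coo = m.tocoo()
        n2 = bn2.chrom_nbins(chrom)
        r, c = coo.row // factor, coo.col // factor
        mats[chrom] = sp.coo_matrix((coo.data, (r, c)), shape=(n2, n2)).tocsr()
    return ContactMatrix(bn2, mats)
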