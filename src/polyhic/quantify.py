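"""Spike-in ChIP calibration and a minimal differential-expression test.

Calibration follows the standard spike-in convention: every sample is
scaled down to the smallest spike-in depth, factor_i = min_j(spikein_j) /
spikein_i, applied by binomial subsampling of target reads. The factors
are invariant to uniform rescaling of all spike-in counts and at least one
factor equals 1.

The differential-expression routine is a deliberately simple stand-in for
a full negative-binomial framework: a Welch-type two-sample test on log2
size-factor-normalised counts, with empirical-Bayes moderation of the
per-group variances (shrunk toward the across-gene mean with a prior
number of degrees of freedom, in the spirit of limma), Benjamini-Hochberg
adjustment, and the significance thresholds padj <= 0.05 and |LFC| >= 0.5.
Genes with a total read count below 10 are excluded before testing. For
fidelity-critical use an externally computed DE table with the same
columns can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CalibrationFactors", "calibration_factors", "subsample_counts",
           "size_factors", "differential_expression", "de_status"]


@dataclass
class CalibrationFactors:
    """Per-sample spike-in calibration: factor in (0, 1], max factor = 1."""

    table: pd.DataFrame  # columns: sample, target_reads, spikein_reads, factor

    @property
    def factors(self) -> pd.Series:
        return self.table.set_index("sample")["factor"]


def calibration_factors(samples: pd.DataFrame) -> CalibrationFactors:
    """factor_i = min_j(spikein_j) / spikein_i.

    `samples` needs columns sample, target_reads, spikein_reads; zero
    spike-in reads is an error naming the sample.
    """
    tab = samples.copy().reset_index(drop=True)
    zeros = tab[tab["spikein_reads"] <= 0]
    if len(zeros):
        raise ValueError("zero spike-in reads for sample(s): "
                         + ", ".join(map(str, zeros["sample"])))
    tab["factor"] = tab["spikein_reads"].min() / tab["spikein_reads"]
    return CalibrationFactors(tab)


def subsample_counts(n_reads: int, factor: float, seed: int = 0) -> int:
    """Random subsampling: retain each of `n_reads` with probability
    `factor` (binomial draw)."""
    if not 0 < factor <= 1:
        raise ValueError("factor must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(int(n_reads), factor))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples table).

    The reference is the per-gene geometric mean over samples (genes with
    a zero anywhere are dropped from the reference, which must remain
    non-empty). Factors are scale-equivariant.
    """
    mat = counts.to_numpy(float)
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene has nonzero counts in all samples")
    logs = np.log(mat[pos])
    ref = logs.mean(axis=1)
    sf = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def de_status(lfc: np.ndarray, padj: np.ndarray, lfc_threshold: float = 0.5,
              alpha: float = 0.05) -> np.ndarray:
    """Map (LFC, padj) to up / down / unchanged by the fixed thresholds."""
    status = np.full(len(lfc), "unchanged", dtype=object)
    sig = np.asarray(padj) <= alpha
    status[sig & (np.asarray(lfc) >= lfc_threshold)] = "up"
    status[sig & (np.asarray(lfc) <= -lfc_threshold)] = "down"
    return status


def differential_expression(counts: pd.DataFrame, groups,
                            lfc_threshold: float = 0.5, alpha: float = 0.05,
                            min_count: int = 10, prior_df: float = 20.0,
                            pseudocount: float = 0.5) -> pd.DataFrame:
    """Two-group moderated Welch test on log2 normalised counts.

    Parameters
    ----------
    counts
        Genes x samples integer table.
    groups
        Sequence of two labels per sample, e.g. ["wt","wt","wt","ko",...];
        LFC is group2 - group1 in order of first appearance.
    prior_df
        Degrees of freedom of the variance prior (0 disables moderation
        and yields the plain Welch test).

    Returns a per-gene DataFrame with base_mean, lfc, pvalue, padj and
    status (up/down/unchanged; "excluded" for genes below `min_count`
    total reads, which carry NaN statistics).
    """
    groups = np.asarray(list(groups))
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(
                f"group {lab!r} has < 2 replicates; supply an external DE table")
    sf = size_factors(counts)
    norm = counts.to_numpy(float) / sf.to_numpy()[None, :]
    keep = counts.sum(axis=1).to_numpy() >= min_count
    y = np.log2(norm + pseudocount)
    i1, i2 = groups == labels[0], groups == labels[1]
    n1, n2 = int(i1.sum()), int(i2.sum())
    m1, m2 = y[:, i1].mean(axis=1), y[:, i2].mean(axis=1)
    v1 = y[:, i1].var(axis=1, ddof=1)
    v2 = y[:, i2].var(axis=1, ddof=1)
    if prior_df > 0:
        # shrink per-gene variances toward the across-gene mean (tested genes)
        p1 = v1[keep].mean() if keep.any() else 0.0
        p2 = v2[keep].mean() if keep.any() else 0.0
        v1 = (prior_df * p1 + (n1 - 1) * v1) / (prior_df + n1 - 1)
        v2 = (prior_df * p2 + (n2 - 1) * v2) / (prior_df + n2 - 1)
        df1, df2 = prior_df + n1 - 1, prior_df + n2 - 1
    else:
        df1, df2 = n1 - 1, n2 - 1
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m2 - m1) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / df1 + (v2 / n2) ** 2 / df2)
    pvals = np.where(se2 > 0, 2 * stats.t.sf(np.abs(t), df), 1.0)
    lfc = m2 - m1
    padj = np.full(len(pvals), np.nan)
    if keep.any():
        padj[keep] = multipletests(pvals[keep], method="fdr_bh")[1]
    status = np.full(len(pvals), "excluded", dtype=object)
    status[keep] = de_status(lfc[keep], padj[keep], lfc_threshold, alpha)
    out = pd.DataFrame({
        "base_mean": norm.mean(axis=1),
        "lfc": np.where(keep, lfc, np.nan),
        "pvalue": np.where(keep, pvals, np.nan),
        "padj": padj,
        "status": status,
    }, index=counts.index)
    return out
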