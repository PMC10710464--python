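"""Two-condition synthetic Hi-C generator with planted ground truth.

The forward model plants, per chromosome: a power-law distance decay,
alternating A/B compartment blocks, TADs, short CTCF loops, and long
Polycomb loops of which a subset is *ultra-long* (spanning many TADs).
The perturbed ("KO") condition emulates cohesin dysregulation: ectopic
insulation boundaries placed inside ultra-long loops, attenuation of the
loops that cross them, weakened compartmentalization, and contact leakage
into neighbouring TADs over a finite genomic reach. Genes at the anchors of
disrupted loops are planted as transcriptionally upregulated.

Expected counts for a pixel at bins (i, j), i < j, are

    lambda_ij = depth * nu_i * nu_j * d_ij**(-alpha) * C_ij * T_ij * L_ij / Z

with per-bin visibility nu (log-normal), compartment factor C (gamma_comp if
the bins share a label, 1/gamma_comp otherwise), TAD factor T (gamma_tad
within a TAD; `leak` for inter-TAD pairs within `leak_reach` bp; 1 beyond),
loop factor L (a Gaussian bump of height `amplitude` and width sigma at each
anchor pair), and Z normalising the total expectation to `depth` per
chromosome. Pixels are independent Poisson draws of the upper triangle; the
diagonal is excluded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .binning import GenomeBinning
from .contact import ContactMatrix, write_contacts, read_contacts

__all__ = [
    "ArchitectureTruth", "SimulationParams", "build_truth",
    "simulate_contact_matrix", "expected_counts", "simulate_features",
    "simulate_expression", "simulate_spikein_counts",
    "write_fixture", "read_fixture", "default_binning", "default_truth",
]

CONDITIONS = ("WT", "KO")

# classification geometry the feature emitter guarantees round-trippable:
# peaks are 2 * PEAK_HALF wide, and gene bins are kept far enough apart that
# a +/- 3 kb TSS window never reaches a neighbouring gene's peaks.
PEAK_HALF = 1000
TSS_WINDOW = 3000


class PlacementError(RuntimeError):
    """Raised when a requested architecture cannot be placed."""


@dataclass
class SimulationParams:
    """Forward-model parameters; per-condition entries are WT/KO dicts."""

    depth: float = 1e7            # expected cis counts per chromosome
    alpha: float = 1.0            # distance-decay exponent
    vis_sd: float = 0.1           # per-bin log-visibility noise sd
    gamma_comp: dict = field(default_factory=lambda: {"WT": 1.4, "KO": 1.15})
    comp_min_dist: float = 2e6    # bp; checkerboard factor acts beyond this
    gamma_tad: float = 2.0
    leak: dict = field(default_factory=lambda: {"WT": 1.0, "KO": 1.5})
    leak_reach: float = 4.5e6     # bp; inter-TAD leak fades out around this span
    ramp_width: float = 1e6       # bp; width of the smooth distance ramps
    sigma_bins: float = 1.0       # loop bump width
    ectopic_depletion: float = 3.0  # KO contact depletion across ectopic sites
    ectopic_reach: float = 5e5    # bp; span of the local ectopic insulation
    seed: int = 0

    def __post_init__(self):
        for name, v in [("alpha", self.alpha), ("gamma_tad", self.gamma_tad),
                        ("sigma_bins", self.sigma_bins)]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        for cond in CONDITIONS:
            if self.gamma_comp[cond] <= 0 or self.leak[cond] <= 0:
                raise ValueError("per-condition factors must be > 0")
        if self.leak["KO"] < self.leak["WT"]:
            raise ValueError("KO leak must be >= WT leak")


@dataclass
class ArchitectureTruth:
    """Planted architecture shared by the simulator and recovery tests.

    ``loops`` columns: chrom, a1, a2 (within-chromosome anchor bins,
    a1 < a2), kind (ctcf|polycomb), ultralong (bool), amp_wt, amp_ko,
    up_anchor (0 = none, 1|2 = the anchor whose gene is planted
    upregulated). ``genes`` columns: gene_id, chrom, tss_bin, gene_class
    (prc1prc2|vprc1|nonpcg|other), lfc.
    """

    binning: GenomeBinning
    compartments: dict            # chrom -> array of 'A'/'B' per bin
    boundaries: dict              # cond -> chrom -> sorted internal boundary bins
    ectopic_boundaries: dict      # chrom -> bins (KO only)
    removed_boundaries: dict      # chrom -> bins (present in WT, absent in KO)
    loops: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self):
        if len(self.loops) and not (self.loops["a1"] < self.loops["a2"]).all():
            raise ValueError("loop anchors must satisfy a1 < a2")
        bad = self.loops[(self.loops["amp_ko"] < self.loops["amp_wt"])]
        for _, lp in bad.iterrows():
            ect = self.ectopic_boundaries.get(lp["chrom"], np.array([]))
            if not np.any((ect > lp["a1"]) & (ect < lp["a2"])):
                raise ValueError("disrupted loop does not cross an ectopic boundary")
        up = self.genes[self.genes["lfc"] > 0]
        anchor_bins = {(lp["chrom"], lp[f"a{int(lp['up_anchor'])}"])
                       for _, lp in bad.iterrows() if lp["up_anchor"]}
        for _, g in up.iterrows():
            if (g["chrom"], g["tss_bin"]) not in anchor_bins:
                raise ValueError("upregulated truth gene not at a disrupted-loop anchor")

    # -- convenience ---------------------------------------------------------

    def compartment_sign(self, chrom: str) -> np.ndarray:
        return np.where(self.compartments[chrom] == "A", 1.0, -1.0)

    def labels_on(self, binning: GenomeBinning) -> dict:
        """Majority-vote compartment labels on a coarser binning."""
        out = {}
        f = binning.binsize // self.binning.binsize
        if f * self.binning.binsize != binning.binsize:
            raise ValueError("coarse binsize must be a multiple of the truth binsize")
        for chrom, lab in self.compartments.items():
            n2 = binning.chrom_nbins(chrom)
            sign = np.where(lab == "A", 1, -1)
            agg = np.array([sign[i * f:(i + 1) * f].sum() for i in range(n2)])
            out[chrom] = np.where(agg >= 0, "A", "B")
        return out

    def tad_intervals(self, condition: str = "WT") -> pd.DataFrame:
        """TADs as bp intervals (chrom, start, end) for one condition."""
        rows = []
        bs = self.binning.binsize
        for chrom in self.binning.chroms:
            n = self.binning.chrom_nbins(chrom)
            b = np.concatenate([[0], self.boundaries[condition][chrom], [n]])
            for s, e in zip(b[:-1], b[1:]):
                rows.append((chrom, int(s) * bs,
                             min(int(e) * bs, self.binning.chromsizes[chrom])))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def loop_intervals(self) -> pd.DataFrame:
        """Loops as BEDPE-style anchor intervals (one bin wide)."""
        bs = self.binning.binsize
        df = self.loops.copy()
        out = pd.DataFrame({
            "chrom1": df["chrom"], "start1": df["a1"] * bs, "end1": (df["a1"] + 1) * bs,
            "chrom2": df["chrom"], "start2": df["a2"] * bs, "end2": (df["a2"] + 1) * bs,
        })
        for col in ("kind", "ultralong", "amp_wt", "amp_ko", "up_anchor"):
            out[col] = df[col].values
        return out

    # -- (de)serialisation ---------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "chromsizes": dict(self.binning.chromsizes),
            "binsize": self.binning.binsize,
            "compartments": {c: "".join(v) for c, v in self.compartments.items()},
            "boundaries": {cond: {c: np.asarray(v).tolist()
                                  for c, v in d.items()}
                           for cond, d in self.boundaries.items()},
            "ectopic_boundaries": {c: np.asarray(v).tolist()
                                   for c, v in self.ectopic_boundaries.items()},
            "removed_boundaries": {c: np.asarray(v).tolist()
                                   for c, v in self.removed_boundaries.items()},
            "loops": self.loops.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path) -> "ArchitectureTruth":
        obj = json.loads(Path(path).read_text())
        binning = GenomeBinning(obj["chromsizes"], obj["binsize"])
        return cls(
            binning=binning,
            compartments={c: np.array(list(s)) for c, s in obj["compartments"].items()},
            boundaries={cond: {c: np.array(v, dtype=int) for c, v in d.items()}
                        for cond, d in obj["boundaries"].items()},
            ectopic_boundaries={c: np.array(v, dtype=int)
                                for c, v in obj["ectopic_boundaries"].items()},
            removed_boundaries={c: np.array(v, dtype=int)
                                for c, v in obj["removed_boundaries"].items()},
            loops=pd.DataFrame(obj["loops"]),
            genes=pd.DataFrame(obj["genes"]),
        )

    def __eq__(self, other):
        return (isinstance(other, ArchitectureTruth)
                and self.binning == other.binning
                and all(np.array_equal(self.compartments[c], other.compartments[c])
                        for c in self.compartments)
                and all(np.array_equal(self.boundaries[k][c], other.boundaries[k][c])
                        for k in self.boundaries for c in self.boundaries[k])
                and self.loops.equals(other.loops)
                and self.genes.equals(other.genes))


# ---------------------------------------------------------------------------

def default_binning() -> GenomeBinning:
    """The default study genome: two 40 Mb chromosomes at 10 kb bins."""
    return GenomeBinning({"chr1": 40_000_000, "chr2": 40_000_000}, 10_000)


def build_truth(binning: GenomeBinning, n_tads: int = 80, n_ctcf_loops: int = 30,
                n_polycomb_loops: int = 20, n_ultralong: int = 6,
                n_genes: int = 150, seed: int = 0, *,
                n_removed_boundaries: int = 2, gamma_loop: float = 3.0,
                attenuation: float = 0.3, up_lfc: float = 3.0,
                min_tad_bins: int | None = None) -> ArchitectureTruth:
    """Plant a two-condition architecture. Counts are per chromosome.

    Ultra-long Polycomb loops span at least ten times the median TAD size;
    each crosses one KO-only ectopic boundary placed a few hundred kb inside
    the loop from its "up" anchor, whose gene is planted with log2 fold
    change `up_lfc`. All other loops have condition-independent amplitude.
    """
    if n_ultralong > n_polycomb_loops:
        raise ValueError("n_ultralong must be <= n_polycomb_loops")
    rng = np.random.default_rng(seed)
    bs = binning.binsize
    compartments, bdr_wt, bdr_ko, ect_all, rem_all = {}, {}, {}, {}, {}
    loop_rows, gene_rows = [], []
    gene_counter = 0
    # minimum spacing (in bins) between gene TSS bins so that emitted peaks
    # never bleed into a neighbouring gene's classification window
    gene_gap = max(1, -(-(TSS_WINDOW + PEAK_HALF + 100) // bs))

    for chrom in binning.chroms:
        n = binning.chrom_nbins(chrom)
        # --- TADs: exponential-tailed sizes >= min_tad_bins ------------------
        # (heavy-tailed sizes, as in real TAD calls, keep same-TAD pixel
        # pairs present at multi-TAD genomic distances)
        g = min_tad_bins if min_tad_bins is not None else \
            max(4, int(round(2.5e5 / bs)))
        if n_tads * g >= n:
            raise PlacementError(
                f"{chrom}: cannot place {n_tads} TADs of >= {g} bins in {n} bins")
        raw = rng.lognormal(0.0, 1.0, n_tads)
        sizes = np.floor(g + raw / raw.sum() * (n - n_tads * g)).astype(int)
        deficit = n - sizes.sum()
        sizes[np.argsort(sizes)[-int(deficit):]] += 1 if deficit else 0
        boundaries = np.cumsum(sizes)[:-1]
        med_tad = int(np.median(sizes))
        # --- compartments: alternating blocks, exponential-tailed lengths ----
        # (block-length variance decorrelates labels at long range, so the
        # same-label pair fraction tends to 1/2 beyond a few blocks)
        labels = np.empty(n, dtype="U1")
        pos, lab = 0, rng.choice(["A", "B"])
        while pos < n:
            blk = max(1, int((8e5 + rng.exponential(1.5e6)) / bs))
            labels[pos:pos + blk] = lab
            pos += blk
            lab = "A" if lab == "B" else "B"
        compartments[chrom] = labels

        occupied: set[int] = set(boundaries.tolist())

        def place(predicate, lo, hi, tries=2000, what="site"):
            for _ in range(tries):
                b = int(rng.integers(lo, hi))
                if b in occupied:
                    continue
                if any(abs(b - o) < gene_gap for o in occupied):
                    continue
                if predicate(b):
                    occupied.add(b)
                    return b
            raise PlacementError(f"{chrom}: could not place {what} after {tries} tries")

        # --- ultra-long Polycomb loops (disrupted in KO) ---------------------
        min_span = 10 * med_tad
        if n_ultralong > 0 and min_span + 2 * gene_gap >= n:
            raise PlacementError(f"{chrom}: ultra-long span {min_span} bins "
                                 f"does not fit in {n} bins")
        ectopic, chrom_loops = [], []
        in_A = lambda b: labels[b] == "A"

        def place_pair(span_lo, span_hi, extra=None, tries=4000, what="loop"):
            """Anchor pair (a1, a1+span), both in A and clear of occupied."""
            for _ in range(tries):
                span = int(rng.integers(span_lo, span_hi + 1))
                if span >= n - 2:
                    continue
                b = int(rng.integers(1, n - span - 1))
                pair = (b, b + span)
                if any(p in occupied or not in_A(p)
                       or any(abs(p - o) < gene_gap for o in occupied)
                       for p in pair):
                    continue
                if extra is not None and not extra(*pair):
                    continue
                occupied.update(pair)
                return pair
            raise PlacementError(f"{chrom}: could not place {what} "
                                 f"after {tries} tries")

        # keep disrupted loops away from chromosome ends: the ectopic site
        # must fall where insulation is measurable (outside the end gaps)
        edge = max(4, int(8e5 / bs))
        for _ in range(n_ultralong):
            a1, a2 = place_pair(min_span, min(int(1.4 * min_span), n - 2),
                                extra=lambda p1, p2: p1 >= edge
                                and p2 <= n - edge,
                                what="ultra-long Polycomb loop")
            up = int(rng.integers(1, 3))   # which anchor carries the up gene
            off = int(rng.integers(20, 51))
            ect = a1 + off if up == 1 else a2 - off
            # keep the ectopic boundary clear of existing boundaries
            while any(abs(ect - b) < 4 for b in occupied):
                ect += 1 if up == 1 else -1
            occupied.add(ect)
            ectopic.append(ect)
            chrom_loops.append((chrom, a1, a2, "polycomb", True,
                                gamma_loop, attenuation * gamma_loop, up))
        # --- other Polycomb loops (stable) -----------------------------------
        # anchors kept clear of ectopic sites so these loops stay intact in KO
        clear = max(2, int(7e5 // bs))
        # spans capped at 1.3 Mb so these loops live where the compartment
        # factor is flat and the leak zone fully covers the pileup window
        span_lo = max(5, min(med_tad, int(1.3e6 / bs) - 3))
        span_hi = max(span_lo + 2, min(4 * med_tad, int(1.3e6 / bs)))
        for _ in range(n_polycomb_loops - n_ultralong):
            a1, a2 = place_pair(
                span_lo, span_hi,
                extra=lambda p1, p2: all(
                    abs(p1 - e) > clear and abs(p2 - e) > clear
                    for e in ectopic),
                what="Polycomb loop")
            chrom_loops.append((chrom, a1, a2, "polycomb", False,
                                gamma_loop, gamma_loop, 0))
        # --- CTCF loops within TADs ------------------------------------------
        tad_edges = np.concatenate([[0], boundaries, [n]])
        big = [t for t in range(len(tad_edges) - 1)
               if tad_edges[t + 1] - tad_edges[t] >= 3 * gene_gap + 4]
        for _ in range(n_ctcf_loops):
            t = big[int(rng.integers(len(big)))]
            lo, hi = int(tad_edges[t]), int(tad_edges[t + 1])
            a1 = place(lambda b: lo < b < hi - 2 * gene_gap - 1,
                       lo + 1, hi - 2 * gene_gap - 1, what="CTCF loop anchor")
            a2 = place(lambda b, a1=a1: a1 + 1 < b < hi,
                       a1 + gene_gap, hi, what="CTCF loop anchor")
            chrom_loops.append((chrom, a1, a2, "ctcf", False, gamma_loop,
                                gamma_loop, 0))
        loop_rows.extend(chrom_loops)

        # --- boundary changes in KO ------------------------------------------
        # removed boundaries stay clear of ectopic sites and of Polycomb
        # loop anchors so their signature is isolated from loop changes
        pcg_anchors = [a for lp in chrom_loops if lp[3] == "polycomb"
                       for a in (lp[1], lp[2])]
        far_from_ect = [b for b in boundaries
                        if all(abs(b - e) > 60 for e in ectopic)
                        and all(abs(b - a) > clear for a in pcg_anchors)]
        n_rem = min(n_removed_boundaries, len(far_from_ect))
        removed = sorted(rng.choice(far_from_ect, size=n_rem, replace=False).tolist()) \
            if n_rem else []
        bdr_wt[chrom] = np.sort(boundaries)
        bdr_ko[chrom] = np.sort(np.array(
            [b for b in boundaries if b not in removed] + ectopic, dtype=int))
        ect_all[chrom] = np.array(sorted(ectopic), dtype=int)
        rem_all[chrom] = np.array(removed, dtype=int)

        # --- genes ------------------------------------------------------------
        pcg_anchor_bins = [(lp[1], lp[4] and lp[7] == 1)
                           for lp in chrom_loops if lp[3] == "polycomb"] + \
                          [(lp[2], lp[4] and lp[7] == 2)
                           for lp in chrom_loops if lp[3] == "polycomb"]
        for b, is_up in pcg_anchor_bins:
            gene_rows.append((f"g{gene_counter:05d}", chrom, b, "prc1prc2",
                              up_lfc if is_up else 0.0))
            gene_counter += 1
        n_rest = n_genes - len(pcg_anchor_bins)
        if n_rest < 0:
            raise PlacementError(f"{chrom}: n_genes smaller than number of "
                                 "Polycomb loop anchors")
        classes = (["prc1prc2"] * int(0.15 * n_rest) + ["vprc1"] * int(0.2 * n_rest)
                   + ["nonpcg"] * int(0.35 * n_rest))
        classes += ["other"] * (n_rest - len(classes))
        for cls in classes:
            pred = in_A if cls == "prc1prc2" else (lambda b: True)
            b = place(pred, 1, n - 1, what=f"{cls} gene TSS")
            gene_rows.append((f"g{gene_counter:05d}", chrom, b, cls, 0.0))
            gene_counter += 1

    loops = pd.DataFrame(loop_rows, columns=[
        "chrom", "a1", "a2", "kind", "ultralong", "amp_wt", "amp_ko", "up_anchor"])
    genes = pd.DataFrame(gene_rows, columns=[
        "gene_id", "chrom", "tss_bin", "gene_class", "lfc"])
    return ArchitectureTruth(binning, compartments,
                             {"WT": bdr_wt, "KO": bdr_ko},
                             ect_all, rem_all, loops, genes)


def default_truth(seed: int = 0, **kwargs) -> ArchitectureTruth:
    return build_truth(default_binning(), seed=seed, **kwargs)


# ---------------------------------------------------------------------------

def _condition_code(condition: str) -> int:
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    return CONDITIONS.index(condition)


def _lambda_chrom(truth: ArchitectureTruth, params: SimulationParams,
                  condition: str, chrom: str, nu: np.ndarray) -> np.ndarray:
    """Dense expected-count matrix (upper triangle, diagonal zero)."""
    bn = truth.binning
    n = bn.chrom_nbins(chrom)
    idx = np.arange(n)
    d = np.abs(idx[None, :] - idx[:, None]).astype(float)
    with np.errstate(divide="ignore"):
        lam = d ** (-params.alpha)
    np.fill_diagonal(lam, 0.0)
    # compartments: the checkerboard factor is a long-range phenomenon; it
    # ramps in smoothly around comp_min_dist (short-range decay is
    # extrusion-driven), avoiding hard O/E steps at the gate distance
    d_bp = d * bn.binsize
    ramp = params.ramp_width
    sign = truth.compartment_sign(chrom)
    gc = params.gamma_comp[condition]
    same = np.equal.outer(sign, sign)
    w_comp = np.clip((d_bp - (params.comp_min_dist - ramp / 2)) / ramp, 0.0, 1.0)
    lam *= np.exp(w_comp * np.where(same, np.log(gc), -np.log(gc)))
    # TADs: gamma_tad within; inter-TAD pairs see the leak factor, fading
    # out smoothly around leak_reach (finite extrusion processivity)
    b = truth.boundaries[condition][chrom]
    tad = np.searchsorted(b, idx, side="right")
    same_tad = np.equal.outer(tad, tad)
    w_leak = 1.0 - np.clip((d_bp - (params.leak_reach - ramp / 2)) / ramp,
                           0.0, 1.0)
    lk = params.leak[condition]
    lam *= np.where(same_tad, params.gamma_tad,
                    np.exp(w_leak * np.log(lk)) if lk != 1.0 else 1.0)
    del d_bp, w_comp, w_leak
    # ectopic insulation sites (KO only): contacts straddling the new
    # boundary are locally depleted, emulating a strong new insulation site
    if condition == "KO" and params.ectopic_depletion != 1.0:
        er = int(params.ectopic_reach / bn.binsize)
        for e in truth.ectopic_boundaries.get(chrom, []):
            lo, hi = max(0, int(e) - er), min(n, int(e) + er)
            lam[lo:e, e:hi] /= params.ectopic_depletion
            lam[e:hi, lo:e] /= params.ectopic_depletion
    # loops
    amp_col = "amp_wt" if condition == "WT" else "amp_ko"
    sig = params.sigma_bins
    half = int(np.ceil(4 * sig))
    for _, lp in truth.loops[truth.loops["chrom"] == chrom].iterrows():
        a1, a2, amp = int(lp["a1"]), int(lp["a2"]), float(lp[amp_col])
        r0, r1 = max(0, a1 - half), min(n, a1 + half + 1)
        c0, c1 = max(0, a2 - half), min(n, a2 + half + 1)
        ri = np.arange(r0, r1)
        ci = np.arange(c0, c1)
        bump = np.exp(-((ri[:, None] - a1) ** 2 + (ci[None, :] - a2) ** 2)
                      / (2 * sig ** 2))
        lam[r0:r1, c0:c1] *= 1.0 + (amp - 1.0) * bump
        lam[c0:c1, r0:r1] *= 1.0 + (amp - 1.0) * bump.T
    # visibility and normalisation to the requested depth
    lam *= np.outer(nu, nu)
    lam = np.triu(lam, k=1)
    tot = lam.sum()
    if not np.isfinite(tot):
        raise OverflowError(f"{chrom}: expected counts overflow")
    if tot > 0:
        lam *= params.depth / tot
    return lam


def _visibility(params: SimulationParams, condition: str, chrom_idx: int,
                n: int) -> np.ndarray:
    rng = np.random.default_rng(
        [params.seed, _condition_code(condition), 101 + chrom_idx])
    return np.exp(rng.normal(0.0, params.vis_sd, n)) if params.vis_sd > 0 \
        else np.ones(n)


def expected_counts(truth: ArchitectureTruth, params: SimulationParams,
                    condition: str, chrom: str,
                    unit_visibility: bool = False) -> np.ndarray:
    """The analytic expectation lambda for one chromosome (upper triangle)."""
    bn = truth.binning
    ci = bn.chroms.index(chrom)
    nu = np.ones(bn.chrom_nbins(chrom)) if unit_visibility else \
        _visibility(params, condition, ci, bn.chrom_nbins(chrom))
    return _lambda_chrom(truth, params, condition, chrom, nu)


def simulate_contact_matrix(truth: ArchitectureTruth, params: SimulationParams,
                            condition: str) -> ContactMatrix:
    """Poisson-sample a cis contact matrix for one condition.

    Deterministic given ``params.seed`` and the condition; the returned
    matrix is symmetric (upper triangle stored), non-negative integer, with
    an empty diagonal.
    """
    bn = truth.binning
    code = _condition_code(condition)
    if params.depth == 0:
        warnings.warn("depth=0: returning an empty contact matrix")
        return ContactMatrix.empty(bn)
    mats = {}
    for ci, chrom in enumerate(bn.chroms):
        n = bn.chrom_nbins(chrom)
        nu = _visibility(params, condition, ci, n)
        lam = _lambda_chrom(truth, params, condition, chrom, nu)
        rng = np.random.default_rng([params.seed, code, 7 + ci])
        counts = rng.poisson(lam)
        mats[chrom] = sp.csr_matrix(counts)
        del lam, counts
    return ContactMatrix(bn, mats)


# ---------------------------------------------------------------------------

def simulate_features(truth: ArchitectureTruth, binning: GenomeBinning,
                      seed: int = 0, n_active_peaks: int = 50) -> dict:
    """Emit peak sets and gene annotation consistent with the planted truth.

    Peaks (each 2 kb, centred on a bin midpoint): BioCap at all NMI gene
    classes (prc1prc2, vprc1, nonpcg); RING1B at prc1prc2 + vprc1 TSSs and
    at Polycomb loop anchors; SUZ12 and CBX7 at prc1prc2 TSSs; PCGF1 at
    vprc1 TSSs; RAD21 and CTCF at TAD boundaries and CTCF loop anchors;
    H3K27ac at random A-compartment bins. Deterministic given `seed`;
    ``classify_tss`` on the output recovers the truth classes exactly.
    """
    rng = np.random.default_rng([seed, 77])
    bs = binning.binsize
    half = min(PEAK_HALF, max(1, bs // 4))

    def peak_at(chrom, b):
        c = b * bs + bs // 2
        return (chrom, max(0, c - half),
                min(binning.chromsizes[chrom], c + half))

    genes = truth.genes
    peaks = {k: [] for k in ["biocap", "ring1b", "suz12", "cbx7", "pcgf1",
                             "rad21", "ctcf", "h3k27ac"]}
    for _, g in genes.iterrows():
        p = peak_at(g["chrom"], g["tss_bin"])
        if g["gene_class"] in ("prc1prc2", "vprc1", "nonpcg"):
            peaks["biocap"].append(p)
        if g["gene_class"] in ("prc1prc2", "vprc1"):
            peaks["ring1b"].append(p)
        if g["gene_class"] == "prc1prc2":
            peaks["suz12"].append(p)
            peaks["cbx7"].append(p)
        if g["gene_class"] == "vprc1":
            peaks["pcgf1"].append(p)
    pcg = truth.loops[truth.loops["kind"] == "polycomb"]
    for _, lp in pcg.iterrows():
        peaks["ring1b"].append(peak_at(lp["chrom"], lp["a1"]))
        peaks["ring1b"].append(peak_at(lp["chrom"], lp["a2"]))
    ctcf_loops = truth.loops[truth.loops["kind"] == "ctcf"]
    for _, lp in ctcf_loops.iterrows():
        for a in (lp["a1"], lp["a2"]):
            p = peak_at(lp["chrom"], a)
            peaks["rad21"].append(p)
            peaks["ctcf"].append(p)
    gene_bins = {(g["chrom"], g["tss_bin"]) for _, g in genes.iterrows()}
    for chrom in binning.chroms:
        for b in truth.boundaries["WT"][chrom]:
            p = peak_at(chrom, int(b))
            peaks["rad21"].append(p)
            peaks["ctcf"].append(p)
        a_bins = np.flatnonzero(truth.compartments[chrom] == "A")
        free = [b for b in a_bins if (chrom, b) not in gene_bins]
        pick = rng.choice(len(free), size=min(n_active_peaks, len(free)),
                          replace=False)
        for i in sorted(pick.tolist()):
            peaks["h3k27ac"].append(peak_at(chrom, free[i]))

    out = {}
    for k, rows in peaks.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).drop_duplicates()
        out[k] = df.sort_values(["chrom", "start"], ignore_index=True)
    gene_tbl = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "chrom": genes["chrom"],
        "tss": genes["tss_bin"] * bs + bs // 2,
        "strand": np.where(np.arange(len(genes)) % 2 == 0, "+", "-"),
    })
    out["genes"] = gene_tbl
    return out


def simulate_expression(truth, n_replicates: int = 3,
                        dispersion: float = 0.1, seed: int = 0,
                        base_mean: float = 200.0, base_sd_log: float = 1.0,
                        libsize_sd: float = 0.2) -> tuple:
    """Negative-binomial count table (gene x sample) with planted truth LFCs.

    `truth` is an :class:`ArchitectureTruth` or a bare gene table with
    gene_id and lfc columns (for expression-only studies). Baseline means
    are log-normal around `base_mean`; KO means are the baseline times
    2**lfc; per-sample library-size factors are log-normal and returned
    alongside.
    Returns (counts DataFrame, truth DataFrame with gene_id/lfc, size factors).
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng([seed, 55])
    genes = truth if isinstance(truth, pd.DataFrame) else truth.genes
    gn = len(genes)
    base = rng.lognormal(np.log(base_mean), base_sd_log, gn)
    samples = [f"wt_{i+1}" for i in range(n_replicates)] + \
              [f"ko_{i+1}" for i in range(n_replicates)]
    sf = np.exp(rng.normal(0.0, libsize_sd, 2 * n_replicates))
    r = 1.0 / dispersion
    cols = {}
    for s, name in enumerate(samples):
        mu = base * (2.0 ** genes["lfc"].to_numpy() if name.startswith("ko") else 1.0)
        mu = mu * sf[s]
        p = r / (r + mu)
        cols[name] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(cols, index=genes["gene_id"].to_numpy())
    counts.index.name = "gene_id"
    de_truth = genes[["gene_id", "lfc"]].copy()
    return counts, de_truth, pd.Series(sf, index=samples, name="size_factor")


def simulate_spikein_counts(n_samples: int, target_depths, spikein_fractions,
                            seed: int = 0) -> pd.DataFrame:
    """Per-sample (target reads, spike-in reads) with binomial partitioning.

    Each of `target_depths[i]` total reads is spike-in with probability
    `spikein_fractions[i]` (e.g. 0.04 for a 4% foreign-genome spike-in).
    """
    depths = np.broadcast_to(np.asarray(target_depths, dtype=np.int64), n_samples)
    fracs = np.broadcast_to(np.asarray(spikein_fractions, dtype=float), n_samples)
    if np.any((fracs <= 0) | (fracs >= 1)):
        raise ValueError("spike-in fractions must lie in (0, 1)")
    rng = np.random.default_rng([seed, 33])
    spike = rng.binomial(depths, fracs)
    return pd.DataFrame({
        "sample": [f"s{i+1}" for i in range(n_samples)],
        "target_reads": depths - spike,
        "spikein_reads": spike,
    })


# -- fixture on disk ---------------------------------------------------------

def write_fixture(outdir, truth: ArchitectureTruth, params: SimulationParams,
                  n_replicates: int = 3, dispersion: float = 0.1) -> dict:
    """Simulate both conditions and write the full fixture directory.

    Layout: contacts_{wt,ko}.tsv (COO), peaks_<factor>.bed, loops.bedpe,
    tads.bed, genes.tsv, counts.tsv, truth.json, chrom.sizes.
    Re-reading with :func:`read_fixture` reproduces the objects bit-exactly.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for cond in CONDITIONS:
        cm = simulate_contact_matrix(truth, params, cond)
        p = out / f"contacts_{cond.lower()}.tsv"
        write_contacts(cm, p)
        files[f"contacts_{cond.lower()}"] = p
    feats = simulate_features(truth, truth.binning, seed=params.seed)
    for k, df in feats.items():
        if k == "genes":
            p = out / "genes.tsv"
            df.to_csv(p, sep="\t", index=False)
        else:
            p = out / f"peaks_{k}.bed"
            df.to_csv(p, sep="\t", header=False, index=False)
        files[k] = p
    truth.tad_intervals("WT").to_csv(out / "tads.bed", sep="\t",
                                     header=False, index=False)
    files["tads"] = out / "tads.bed"
    truth.loop_intervals().to_csv(out / "loops.bedpe", sep="\t", index=False)
    files["loops"] = out / "loops.bedpe"
    counts, de_truth, sf = simulate_expression(
        truth, n_replicates=n_replicates, dispersion=dispersion,
        seed=params.seed)
    counts.to_csv(out / "counts.tsv", sep="\t")
    files["counts"] = out / "counts.tsv"
    truth.to_json(out / "truth.json")
    files["truth"] = out / "truth.json"
    with open(out / "chrom.sizes", "w") as fh:
        for c, L in truth.binning.chromsizes.items():
            fh.write(f"{c}\t{L}\n")
    files["chromsizes"] = out / "chrom.sizes"
    return files


def read_fixture(indir) -> dict:
    """Load a fixture directory back into in-memory objects."""
    ind = Path(indir)
    truth = ArchitectureTruth.from_json(ind / "truth.json")
    bn = truth.binning
    out = {"truth": truth, "binning": bn}
    for cond in CONDITIONS:
        out[f"contacts_{cond.lower()}"] = read_contacts(
            ind / f"contacts_{cond.lower()}.tsv", bn)
    for bed in ind.glob("peaks_*.bed"):
        name = bed.stem.replace("peaks_", "")
        out[f"peaks_{name}"] = pd.read_csv(
            bed, sep="\t", names=["chrom", "start", "end"])
    out["genes"] = pd.read_csv(ind / "genes.tsv", sep="\t")
    out["tads"] = pd.read_csv(ind / "tads.bed", sep="\t",
                              names=["chrom", "start", "end"])
    out["loops"] = pd.read_csv(ind / "loops.bedpe", sep="\t")
    out["counts"] = pd.read_csv(ind / "counts.tsv", sep="\t", index_col=0)
    return out
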