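import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import polyhic as ph
from polyhic import GenomeBinning, Track
from polyhic.features import _IntervalIndex, TSS_WINDOW


# -- brute-force oracles -----------------------------------------------------

def brute_overlaps(intervals, chrom, q0, q1):
    return any(c == chrom and s < q1 and e > q0
               for c, s, e in intervals.itertuples(index=False))


def brute_distance(intervals, chrom, pos):
    best = np.nan
    for c, s, e in intervals.itertuples(index=False):
        if c != chrom:
            continue
        if s <= pos < e:
            d = 0
        elif pos < s:
            d = s - pos
        else:
            d = pos - e + 1
        best = d if np.isnan(best) else min(best, d)
    return best


def brute_classify(tss, intervals_by_factor, window=TSS_WINDOW):
    chrom, pos = tss
    q0, q1 = max(pos - window, 0), pos + window
    nmi = brute_overlaps(intervals_by_factor["biocap"], chrom, q0, q1)
    if not nmi:
        return "other"
    r = brute_overlaps(intervals_by_factor["ring1b"], chrom, q0, q1)
    s = brute_overlaps(intervals_by_factor["suz12"], chrom, q0, q1)
    if r and s:
        return "prc1prc2"
    if r:
        return "vprc1"
    return "nonpcg"


def _random_intervals(rng, n, span=100_000, chroms=("chr1", "chr2")):
    chrom = rng.choice(chroms, n)
    start = rng.integers(0, span, n)
    length = rng.integers(1, 5_000, n)
    return pd.DataFrame({"chrom": chrom, "start": start,
                         "end": start + length})


@pytest.mark.parametrize("seed", range(20))
def test_interval_index_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    peaks = _random_intervals(rng, rng.integers(0, 30))
    idx = _IntervalIndex(peaks)
    for _ in range(10):
        chrom = rng.choice(["chr1", "chr2"])
        q0 = int(rng.integers(0, 110_000))
        q1 = q0 + int(rng.integers(1, 10_000))
        assert idx.overlaps(chrom, q0, q1)[0] == \
            brute_overlaps(peaks, chrom, q0, q1)
        pos = int(rng.integers(0, 110_000))
        got = idx.distance(chrom, pos)[0]
        want = brute_distance(peaks, chrom, pos)
        assert (np.isnan(got) and np.isnan(want)) or got == want


@pytest.mark.parametrize("seed", range(10))
def test_classify_tss_matches_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    factors = {k: _random_intervals(rng, rng.integers(0, 25))
               for k in ("biocap", "ring1b", "suz12")}
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(50)],
        "chrom": rng.choice(["chr1", "chr2"], 50),
        "tss": rng.integers(0, 105_000, 50)})
    got = ph.classify_tss(genes, factors["biocap"], factors["ring1b"],
                          factors["suz12"])
    for _, row in got.iterrows():
        assert row["gene_class"] == brute_classify(
            (row["chrom"], row["tss"]), factors)


def test_gene_classes_partition_the_gene_set():
    rng = np.random.default_rng(5)
    factors = {k: _random_intervals(rng, 15)
               for k in ("biocap", "ring1b", "suz12")}
    genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(200)],
                          "chrom": rng.choice(["chr1", "chr2"], 200),
                          "tss": rng.integers(0, 105_000, 200)})
    got = ph.classify_tss(genes, **{k: factors[k] for k in factors})
    assert len(got) == 200
    assert set(got["gene_class"]) <= {"prc1prc2", "vprc1", "nonpcg", "other"}
    assert got["gene_class"].value_counts().sum() == 200


def test_classify_tss_rejects_unknown_chromosome():
    genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chrZ"], "tss": [100]})
    empty = pd.DataFrame(columns=["chrom", "start", "end"])
    with pytest.raises(ValueError, match="unknown"):
        ph.classify_tss(genes, empty, empty, empty,
                        chromsizes={"chr1": 1_000_000})


# -- loop classification -----------------------------------------------------

def _loops(rows):
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                       "chrom2", "start2", "end2"])


def _genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "gene_class"])
    return df


def test_loop_classification_rules():
    ring1b = pd.DataFrame({"chrom": ["chr1", "chr1"],
                           "start": [10_000, 500_000],
                           "end": [12_000, 502_000]})
    genes = _genes([("a", "chr1", 11_000, "prc1prc2"),
                    ("b", "chr1", 501_000, "prc1prc2")])
    loops = _loops([
        ("chr1", 9_000, 13_000, "chr1", 499_000, 503_000),   # both anchors
        ("chr1", 9_000, 13_000, "chr1", 700_000, 704_000),   # one anchor only
    ])
    got = ph.classify_loops(loops, ring1b, genes)
    assert got["pcg_class"].tolist() == ["prc1prc2", "nonpcg"]
    # single-anchor rule upgrades the second loop to pcg
    loose = ph.classify_loops(loops, ring1b, genes, require_both_anchors=False)
    assert loose["pcg_class"].tolist() == ["prc1prc2", "pcg"]


def test_malformed_anchor_raises():
    bad = _loops([("chr1", 13_000, 9_000, "chr1", 499_000, 503_000)])
    ring1b = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1]})
    with pytest.raises(ValueError, match="malformed"):
        ph.classify_loops(bad, ring1b, _genes([]))


def test_fixture_loops_recover_truth_kinds(small_truth):
    from polyhic import simulate as sim
    feats = sim.simulate_features(small_truth, small_truth.binning, seed=7)
    genes = ph.classify_tss(feats["genes"], feats["biocap"], feats["ring1b"],
                            feats["suz12"])
    loops = ph.classify_loops(small_truth.loop_intervals(), feats["ring1b"],
                              genes)
    want = np.where(small_truth.loops["kind"] == "polycomb", "prc1prc2",
                    "nonpcg")
    assert loops["pcg_class"].tolist() == list(want)


# -- bifurcation -------------------------------------------------------------

def test_bifurcation_rules_and_side_labels():
    genes = _genes([("a", "chr1", 11_000, "prc1prc2"),
                    ("b", "chr1", 501_000, "prc1prc2"),
                    ("c", "chr1", 800_000, "prc1prc2")])
    genes["de_status"] = ["unchanged", "up", "unchanged"]
    loops = _loops([
        ("chr1", 9_000, 13_000, "chr1", 499_000, 503_000),  # right anchor up
        ("chr1", 9_000, 13_000, "chr1", 798_000, 802_000),  # no up anchor
        ("chr1", 100_000, 104_000, "chr1", 200_000, 204_000),  # no gene
    ])
    loops["pcg_class"] = "prc1prc2"
    got = ph.bifurcate_loops(loops, genes)
    assert got["bifurcation"].tolist() == ["up", "not_up", "na"]
    assert got.loc[0, "side1"] == "unchanged" and got.loc[0, "side2"] == "up"


def test_bifurcation_is_monotone_in_upregulation():
    genes = _genes([("a", "chr1", 11_000, "prc1prc2"),
                    ("b", "chr1", 501_000, "prc1prc2")])
    loops = _loops([("chr1", 9_000, 13_000, "chr1", 499_000, 503_000)])
    loops["pcg_class"] = "prc1prc2"
    genes["de_status"] = ["unchanged", "unchanged"]
    before = ph.bifurcate_loops(loops, genes)["bifurcation"].iloc[0]
    genes["de_status"] = ["unchanged", "up"]
    after = ph.bifurcate_loops(loops, genes)["bifurcation"].iloc[0]
    assert (before, after) == ("not_up", "up")


# -- loop geometry -----------------------------------------------------------

def test_tads_traversed_examples():
    bn = GenomeBinning({"chr1": 1_000_000}, 10_000)
    comp = ph.compartment_track_from_labels(
        bn, {"chr1": np.array(["A"] * 100)})
    tads = pd.DataFrame({"chrom": "chr1",
                         "start": [100_000, 300_000, 500_000, 700_000],
                         "end": [300_000, 500_000, 700_000, 900_000]})
    loops = _loops([
        ("chr1", 50_000, 60_000, "chr1", 940_000, 950_000),   # 4 interior
        ("chr1", 110_000, 120_000, "chr1", 150_000, 160_000),  # same TAD
    ])
    geo = ph.loop_geometry(loops, tads, comp)
    assert geo["tads_traversed"].tolist() == [4, 0]
    assert geo["length"].iloc[0] == 890_000


def test_traversal_restricted_to_loop_compartment():
    bn = GenomeBinning({"chr1": 1_000_000}, 10_000)
    labels = np.array(["A"] * 50 + ["B"] * 50)
    comp = ph.compartment_track_from_labels(bn, {"chr1": labels})
    tads = pd.DataFrame({"chrom": "chr1",
                         "start": [100_000, 600_000],
                         "end": [300_000, 800_000]})
    # loop in A spanning the whole chromosome: only the A-compartment TAD counts
    loops = _loops([("chr1", 0, 10_000, "chr1", 990_000, 1_000_000)])
    geo = ph.loop_geometry(loops, tads, comp)
    assert geo["tads_traversed"].iloc[0] == 1


@pytest.mark.parametrize("seed", range(10))
def test_tads_traversed_matches_brute_force(seed):
    rng = np.random.default_rng(300 + seed)
    bn = GenomeBinning({"chr1": 2_000_000}, 10_000)
    comp = ph.compartment_track_from_labels(
        bn, {"chr1": rng.choice(["A", "B"], 200)})
    starts = np.sort(rng.choice(np.arange(0, 1_900_000, 10_000), 8,
                                replace=False))
    tads = pd.DataFrame({"chrom": "chr1", "start": starts[:-1],
                         "end": starts[1:]})
    loops = _loops([("chr1", int(a), int(a) + 10_000,
                     "chr1", int(b), int(b) + 10_000)
                    for a, b in [(sorted(rng.integers(0, 1_900_000, 2)))
                                 for _ in range(10)] if a < b])
    geo = ph.loop_geometry(loops, tads, comp)
    labels = comp.chrom_labels("chr1")

    def majority(lo, hi):
        seg = labels[lo // 10_000: hi // 10_000 + 1]
        return "A" if (seg == "A").sum() >= (seg == "B").sum() else "B"

    for _, row in geo.iterrows():
        mid1 = (row["start1"] + row["end1"]) // 2
        mid2 = (row["start2"] + row["end2"]) // 2
        lab = majority(mid1, mid2 - 1)
        want = sum(1 for t in tads.itertuples()
                   if t.start > mid1 and t.end < mid2
                   and majority(t.start, t.end - 1) == lab)
        assert row["tads_traversed"] == want


# -- distances ---------------------------------------------------------------

def test_distance_examples():
    targets = pd.DataFrame({"chrom": ["chr1"], "start": [2_000],
                            "end": [3_000]})
    queries = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                            "tss": [1_000, 2_500, 7]})
    d = ph.distance_to_nearest(queries, targets)
    assert d.iloc[0] == 1_000
    assert d.iloc[1] == 0
    assert np.isnan(d.iloc[2])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_distance_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    targets = _random_intervals(rng, int(rng.integers(0, 12)))
    queries = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 8),
                            "tss": rng.integers(0, 110_000, 8)})
    got = ph.distance_to_nearest(queries, targets)
    for i, row in queries.iterrows():
        want = brute_distance(targets, row["chrom"], row["tss"])
        assert (np.isnan(got.iloc[i]) and np.isnan(want)) or \
            got.iloc[i] == want


def test_rank_sum_direction():
    assert ph.rank_sum_less(np.arange(10), np.arange(100, 110)) < 0.01
    assert ph.rank_sum_less(np.arange(100, 110), np.arange(10)) > 0.9


# -- meta profiles -----------------------------------------------------------

def test_constant_track_gives_constant_profile():
    bn = GenomeBinning({"chr1": 1_000_000}, 10_000)
    tr = Track(bn, np.full(bn.n_bins, 2.5))
    iv = pd.DataFrame({"chrom": ["chr1"] * 3,
                       "start": [200_000, 400_000, 600_000],
                       "end": [210_000, 410_000, 610_000]})
    prof = ph.meta_profile(tr, iv, flank=50_000)
    assert np.allclose(prof["mean"], 2.5)
    assert len(prof) == 11


def test_single_interval_profile_is_the_sliced_track():
    bn = GenomeBinning({"chr1": 1_000_000}, 10_000)
    tr = Track(bn, np.arange(bn.n_bins, dtype=float))
    iv = pd.DataFrame({"chrom": ["chr1"], "start": [500_000],
                       "end": [510_000]})
    prof = ph.meta_profile(tr, iv, flank=30_000)
    assert prof["mean"].tolist() == [47, 48, 49, 50, 51, 52, 53]


def test_minus_strand_profiles_are_flipped():
    bn = GenomeBinning({"chr1": 1_000_000}, 10_000)
    tr = Track(bn, np.arange(bn.n_bins, dtype=float))
    iv = pd.DataFrame({"chrom": ["chr1"], "start": [500_000],
                       "end": [510_000], "strand": ["-"]})
    prof = ph.meta_profile(tr, iv, flank=30_000)
    assert prof["mean"].tolist() == [53, 52, 51, 50, 49, 48, 47]


def test_profile_mean_invariant_to_order_and_duplication():
    rng = np.random.default_rng(2)
    bn = GenomeBinning({"chr1": 1_000_000}, 10_000)
    tr = Track(bn, rng.normal(size=bn.n_bins))
    iv = pd.DataFrame({"chrom": ["chr1"] * 4,
                       "start": [100_000, 300_000, 500_000, 700_000],
                       "end": [110_000, 310_000, 510_000, 710_000]})
    a = ph.meta_profile(tr, iv, flank=50_000)["mean"]
    b = ph.meta_profile(tr, iv.iloc[::-1], flank=50_000)["mean"]
    assert np.allclose(a, b)
    dup = ph.meta_profile(tr, pd.concat([iv, iv]), flank=50_000)["mean"]
    assert np.allclose(a, dup)


def test_empty_interval_set_raises():
    bn = GenomeBinning({"chr1": 100_000}, 10_000)
    tr = Track(bn, np.zeros(bn.n_bins))
    with pytest.raises(ValueError, match="empty"):
        ph.meta_profile(tr, pd.DataFrame(columns=["chrom", "start", "end"]),
                        flank=10_000)
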