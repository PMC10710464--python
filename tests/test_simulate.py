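import numpy as np
import pandas as pd
import pytest

import polyhic as ph
from polyhic import simulate as sim
from polyhic.features import classify_tss


def _tiny_binning(n=30, binsize=10_000):
    return ph.GenomeBinning({"chr1": n * binsize}, binsize)


# -- build_truth -------------------------------------------------------------

def test_no_ultralong_means_no_perturbation(small_binning):
    truth = sim.build_truth(small_binning, n_tads=16, n_ctcf_loops=2,
                            n_polycomb_loops=3, n_ultralong=0, n_genes=20,
                            seed=3)
    assert (truth.loops["amp_wt"] == truth.loops["amp_ko"]).all()
    assert (truth.genes["lfc"] == 0).all()
    assert all(len(v) == 0 for v in truth.ectopic_boundaries.values())


def test_tad_count_fixes_boundary_count():
    bn = ph.GenomeBinning({"chr1": 4_000_000}, 10_000)
    truth = sim.build_truth(bn, n_tads=4, n_ctcf_loops=0, n_polycomb_loops=0,
                            n_ultralong=0, n_genes=5, seed=0)
    b = truth.boundaries["WT"]["chr1"]
    assert len(b) == 3
    assert (np.diff(b) > 0).all()


def test_build_truth_is_deterministic(small_binning):
    kw = dict(n_tads=16, n_ctcf_loops=3, n_polycomb_loops=3, n_ultralong=1,
              n_genes=25, seed=8)
    assert sim.build_truth(small_binning, **kw) == \
        sim.build_truth(small_binning, **kw)


def test_truth_invariants(small_truth):
    t = small_truth
    assert (t.loops["a1"] < t.loops["a2"]).all()
    med = {c: np.median(np.diff(np.concatenate(
        [[0], t.boundaries["WT"][c], [t.binning.chrom_nbins(c)]])))
        for c in t.binning.chroms}
    for _, lp in t.loops[t.loops["ultralong"]].iterrows():
        assert lp["a2"] - lp["a1"] >= 10 * med[lp["chrom"]]
        ect = t.ectopic_boundaries[lp["chrom"]]
        assert np.any((ect > lp["a1"]) & (ect < lp["a2"]))
    # upregulated genes sit at anchors of disrupted loops, in the A compartment
    up = t.genes[t.genes["lfc"] > 0]
    assert len(up) > 0
    for _, g in up.iterrows():
        assert t.compartments[g["chrom"]][g["tss_bin"]] == "A"


def test_infeasible_placement_raises():
    bn = _tiny_binning(n=20)
    with pytest.raises(sim.PlacementError):
        sim.build_truth(bn, n_tads=30, n_ctcf_loops=0, n_polycomb_loops=0,
                        n_ultralong=0, n_genes=1, seed=0)


# -- simulate_contact_matrix -------------------------------------------------

def test_pure_decay_matches_closed_form_expectation():
    """Monte-Carlo mean over 200 replicates vs the analytic lambda."""
    bn = _tiny_binning(n=30)
    truth = sim.build_truth(bn, n_tads=2, n_ctcf_loops=0, n_polycomb_loops=0,
                            n_ultralong=0, n_genes=2, seed=1, min_tad_bins=5,
                            gamma_loop=1.0)
    p = sim.SimulationParams(
        depth=5e4, alpha=1.0, vis_sd=0.0, gamma_comp={"WT": 1, "KO": 1},
        gamma_tad=1.0, leak={"WT": 1, "KO": 1}, ectopic_depletion=1.0, seed=1)
    lam = sim.expected_counts(truth, p, "WT", "chr1", unit_visibility=True)
    acc = np.zeros_like(lam)
    reps = 200
    for r in range(reps):
        p_r = sim.SimulationParams(
            depth=5e4, alpha=1.0, vis_sd=0.0, gamma_comp={"WT": 1, "KO": 1},
            gamma_tad=1.0, leak={"WT": 1, "KO": 1}, ectopic_depletion=1.0,
            seed=1000 + r)
        acc += sim.simulate_contact_matrix(truth, p_r, "WT").dense("chr1")
    mean = np.triu(acc, 1) / reps
    # every distance's mean within 3 standard errors of lambda
    for s in (1, 3, 7, 15):
        d_obs = np.diagonal(mean, s).sum()
        d_exp = np.diagonal(lam, s).sum()
        se = np.sqrt(d_exp / reps)
        assert abs(d_obs - d_exp) < 3.5 * se
    # and E[count at distance s] follows depth * s^-alpha * normalizer
    assert np.diagonal(lam, 2).mean() / np.diagonal(lam, 4).mean() == \
        pytest.approx(2.0, rel=1e-6)


def test_loop_pixel_is_enriched_by_its_amplitude():
    bn = _tiny_binning(n=40)
    truth = sim.build_truth(bn, n_tads=2, n_ctcf_loops=1, n_polycomb_loops=0,
                            n_ultralong=0, n_genes=2, seed=2, min_tad_bins=12,
                            gamma_loop=3.0)
    p = sim.SimulationParams(
        depth=2e5, vis_sd=0.0, gamma_comp={"WT": 1, "KO": 1}, gamma_tad=1.0,
        leak={"WT": 1, "KO": 1}, ectopic_depletion=1.0, seed=2)
    lp = truth.loops.iloc[0]
    a1, a2, s = int(lp["a1"]), int(lp["a2"]), int(lp["a2"] - lp["a1"])
    acc_anchor, acc_bg, nbg = 0.0, 0.0, 0
    for r in range(150):
        p_r = sim.SimulationParams(
            depth=2e5, vis_sd=0.0, gamma_comp={"WT": 1, "KO": 1},
            gamma_tad=1.0, leak={"WT": 1, "KO": 1}, ectopic_depletion=1.0,
            seed=5000 + r)
        d = sim.simulate_contact_matrix(truth, p_r, "WT").dense("chr1")
        acc_anchor += d[a1, a2]
        diag = np.diagonal(d, s)
        far = [i for i in range(len(diag)) if abs(i - a1) > 4]
        acc_bg += np.mean([diag[i] for i in far])
    ratio = acc_anchor / acc_bg
    assert ratio == pytest.approx(3.0, rel=0.15)


def test_zero_depth_returns_empty_matrix(small_truth):
    p = sim.SimulationParams(depth=0, seed=0)
    with pytest.warns(UserWarning, match="depth"):
        cm = sim.simulate_contact_matrix(small_truth, p, "WT")
    assert cm.total() == 0


def test_matrices_are_symmetric_integer_with_empty_diagonal(small_matrices,
                                                            small_params):
    cm = small_matrices["WT"]
    d = cm.dense("chr1")
    assert np.allclose(d, d.T)
    assert np.allclose(d, np.round(d))
    assert np.allclose(np.diagonal(d), 0.0)
    # total counts within 5 sigma of the requested depth (2 chromosomes)
    depth = small_params.depth * len(cm.binning.chroms)
    assert abs(cm.total() - depth) < 5 * np.sqrt(depth)


def test_same_seed_reproduces_matrix(small_truth, small_params):
    a = sim.simulate_contact_matrix(small_truth, small_params, "KO")
    b = sim.simulate_contact_matrix(small_truth, small_params, "KO")
    assert (a.counts["chr1"] != b.counts["chr1"]).nnz == 0


# -- simulate_features -------------------------------------------------------

def test_feature_round_trip_recovers_every_gene_class(small_truth):
    feats = sim.simulate_features(small_truth, small_truth.binning, seed=7)
    got = classify_tss(feats["genes"], feats["biocap"], feats["ring1b"],
                       feats["suz12"])
    assert got["gene_class"].tolist() == small_truth.genes["gene_class"].tolist()


def test_feature_placement_follows_truth(small_truth):
    feats = sim.simulate_features(small_truth, small_truth.binning, seed=7)
    bs = small_truth.binning.binsize
    g = small_truth.genes
    prc = g[g["gene_class"] == "prc1prc2"].iloc[0]
    center = prc["tss_bin"] * bs + bs // 2
    for factor in ("biocap", "ring1b", "suz12", "cbx7"):
        df = feats[factor]
        hit = ((df["chrom"] == prc["chrom"]) & (df["start"] <= center)
               & (df["end"] > center))
        assert hit.any(), factor
    other = g[g["gene_class"] == "other"].iloc[0]
    center = other["tss_bin"] * bs + bs // 2
    df = feats["biocap"]
    near = ((df["chrom"] == other["chrom"])
            & (df["start"] < center + 3000) & (df["end"] > center - 3000))
    assert not near.any()


def test_features_deterministic(small_truth):
    a = sim.simulate_features(small_truth, small_truth.binning, seed=3)
    b = sim.simulate_features(small_truth, small_truth.binning, seed=3)
    for k in a:
        pd.testing.assert_frame_equal(a[k], b[k])


# -- simulate_expression -----------------------------------------------------

def test_null_expression_has_zero_mean_log_ratio():
    genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(400)],
                          "lfc": 0.0})
    counts, _, sf = sim.simulate_expression(genes, n_replicates=3, seed=4,
                                            libsize_sd=0.0)
    wt = counts.iloc[:, :3].mean(axis=1)
    ko = counts.iloc[:, 3:].mean(axis=1)
    lr = np.log2((ko + 0.5) / (wt + 0.5))
    assert abs(lr.mean()) < 3 * lr.std() / np.sqrt(len(lr))


def test_planted_fold_change_is_recovered():
    genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(300)],
                          "lfc": 2.0})
    counts, _, _ = sim.simulate_expression(
        genes, n_replicates=3, dispersion=0.05, seed=5, base_mean=500,
        base_sd_log=0.1, libsize_sd=0.0)
    ratio = counts.iloc[:, 3:].mean(axis=1) / counts.iloc[:, :3].mean(axis=1)
    assert np.median(ratio) == pytest.approx(4.0, rel=0.1)


def test_expression_table_is_deterministic(small_truth):
    a, _, _ = sim.simulate_expression(small_truth, n_replicates=2, seed=6)
    b, _, _ = sim.simulate_expression(small_truth, n_replicates=2, seed=6)
    pd.testing.assert_frame_equal(a, b)


def test_expression_input_validation(small_truth):
    with pytest.raises(ValueError, match="replicates"):
        sim.simulate_expression(small_truth, n_replicates=1)
    with pytest.raises(ValueError, match="dispersion"):
        sim.simulate_expression(small_truth, dispersion=0.0)


# -- spike-in ----------------------------------------------------------------

def test_spikein_fraction_is_binomial():
    tab = sim.simulate_spikein_counts(4, 1_000_000, 0.04, seed=1)
    exp, sd = 40_000, np.sqrt(1e6 * 0.04 * 0.96)
    assert ((tab["spikein_reads"] - exp).abs() < 3.5 * sd).all()
    assert (tab["target_reads"] + tab["spikein_reads"] == 1_000_000).all()


def test_spikein_rejects_bad_fraction():
    with pytest.raises(ValueError):
        sim.simulate_spikein_counts(2, 1000, 1.5, seed=0)


# -- fixture I/O -------------------------------------------------------------

def test_fixture_round_trip(small_fixture_dir, small_truth):
    data = sim.read_fixture(small_fixture_dir)
    assert data["truth"] == small_truth
    assert set(data) >= {"contacts_wt", "contacts_ko", "genes", "tads",
                         "loops", "counts", "peaks_ring1b"}
    assert len(data["loops"]) == len(small_truth.loops)


def test_fixture_contact_files_round_trip(small_fixture_dir, small_truth,
                                          small_params):
    data = sim.read_fixture(small_fixture_dir)
    fresh = sim.simulate_contact_matrix(small_truth, small_params, "WT")
    assert (data["contacts_wt"].counts["chr1"] !=
            fresh.counts["chr1"]).nnz == 0
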