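"""Polycomb gene/loop classification and the loop-bifurcation analysis.

Classifies TSSs from peak occupancy (BioCap + RING1B + SUZ12), labels
Polycomb loops, couples them to differential expression, and measures
aggregate loop strength per class in both conditions — the analysis that
shows disrupted ("up") loops lose contact while intact ("not up") loops
do not.
"""

import polyhic as ph
from polyhic import simulate as sim

truth = sim.default_truth(seed=0)
params = sim.SimulationParams(seed=0)
cm = {c: sim.simulate_contact_matrix(truth, params, c) for c in ("WT", "KO")}
for c in cm:
    ph.ice_balance(cm[c])

feats = sim.simulate_features(truth, truth.binning, seed=0)
genes = ph.classify_tss(feats["genes"], feats["biocap"], feats["ring1b"],
                        feats["suz12"])
print("gene classes:", genes["gene_class"].value_counts().to_dict())

counts, _, _ = sim.simulate_expression(truth, seed=0)
de = ph.differential_expression(counts, ["wt"] * 3 + ["ko"] * 3)
genes = genes.merge(de["status"].rename("de_status"), left_on="gene_id",
                    right_index=True)

loops = ph.classify_loops(truth.loop_intervals(), feats["ring1b"], genes)
loops = ph.bifurcate_loops(loops, genes)
print("loop classes:", loops["pcg_class"].value_counts().to_dict())
print("bifurcation:", loops["bifurcation"].value_counts().to_dict())

window = 21 * truth.binning.binsize
for name in ("up", "not_up"):
    sub = loops[loops["bifurcation"] == name]
    e = {c: ph.loop_pileup(cm[c], sub, window=window).enrichment for c in cm}
    print(f"{name:7s}: WT enrichment {e['WT']:.2f}, KO {e['KO']:.2f}, "
          f"KO/WT = {e['KO'] / e['WT']:.2f}")
# "up" loops (anchored at derepressed genes) lose roughly half their
# aggregate contact strength in KO; "not up" loops are unchanged — contact
# loss, not chromatin-domain loss, tracks with loss of silencing.
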