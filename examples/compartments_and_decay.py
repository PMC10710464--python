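"""A/B compartments, compartment strength, and distance-decay comparison.

The KO-like condition weakens compartmentalization (checkerboard factor
1.15 vs 1.4) without switching labels, and shifts contacts from the
compartment scale (>5 Mb) to the extrusion scale (0.5-5 Mb) — the
signature of unrestricted cohesin loop extrusion.
"""

import numpy as np

import polyhic as ph
from polyhic import simulate as sim

binning = ph.GenomeBinning({"chr1": 40_000_000, "chr2": 40_000_000}, 250_000)
truth = sim.build_truth(binning, n_tads=8, n_ctcf_loops=0,
                        n_polycomb_loops=2, n_ultralong=0, n_genes=20, seed=4)
params = sim.SimulationParams(seed=4, depth=2e6)
orientation = ph.compartment_track_from_labels(
    binning, truth.compartments).track

for cond in ("WT", "KO"):
    cm = sim.simulate_contact_matrix(truth, params, cond)
    ph.ice_balance(cm)
    comp = ph.eigenvector_compartments(cm, orientation)
    agree = np.mean([(comp.chrom_labels(c) == truth.compartments[c]).mean()
                     for c in binning.chroms])
    strength = ph.compartment_strength(cm, comp)["genome"]
    curve = ph.rcp_curve(cm, min_dist=500_000, max_dist=30_000_000,
                         label=cond)
    print(f"{cond}: label agreement {100 * agree:.1f}%, "
          f"compartment strength {strength:.2f}")
# Strength = log2(AA*BB/AB^2) over long-range top-quantile bins: ~2 for a
# well-compartmentalised map, lower in KO — labels stay put, only the
# contrast fades, as in cohesin-unloading mutants.
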