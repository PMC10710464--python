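"""Build a synthetic two-condition Hi-C study with planted ground truth.

Plants compartments, TADs, CTCF loops and ultra-long Polycomb loops on a
small genome, simulates Poisson contact maps for a wild-type-like (WT) and
a cohesin-dysregulated (KO) condition, and writes the fixture directory
(COO contact tables, BED peaks, BEDPE loops, gene/expression tables,
truth JSON).
"""

import polyhic as ph
from polyhic import simulate as sim

binning = ph.GenomeBinning({"chr1": 20_000_000}, 10_000)
truth = sim.build_truth(binning, n_tads=40, n_ctcf_loops=10,
                        n_polycomb_loops=8, n_ultralong=2, n_genes=60,
                        seed=1)
params = sim.SimulationParams(seed=1, depth=4e6)
files = sim.write_fixture("scratch_fixture", truth, params)

ul = truth.loops[truth.loops["ultralong"]]
print(f"planted {len(truth.loops)} loops "
      f"({(truth.loops['kind'] == 'polycomb').sum()} Polycomb, "
      f"{len(ul)} ultra-long and disrupted in KO)")
print(f"ultra-long spans (bp): "
      f"{((ul['a2'] - ul['a1']) * binning.binsize).tolist()}")
print(f"ectopic KO insulation sites at bins: "
      f"{truth.ectopic_boundaries['chr1'].tolist()}")
print(f"upregulated truth genes: "
      f"{truth.genes[truth.genes['lfc'] > 0]['gene_id'].tolist()}")
print(f"wrote {len(files)} files to scratch_fixture/")
# The disrupted loops each cross one ectopic boundary, and the genes at
# their "up" anchors carry a planted log2 fold change — the ground truth
# every downstream analysis is tested against.
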