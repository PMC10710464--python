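"""Run the complete WT-vs-KO comparison and print the summary highlights.

Drives every stage (balancing, compartments, RCP, insulation, pileups,
boundary violation, classification, expression coupling, distances) on
the default synthetic study and writes the report directory.
"""

import json

from polyhic.pipeline import PipelineConfig, run_comparison, report

bundle = run_comparison(PipelineConfig(seed=0))
files = report(bundle, "scratch_report")
s = bundle["summary"]

print("compartment strength:", s["compartment_strength"])
print("RCP log2 KO/WT:", s["rcp_log2_ratio"])
print("insulation:", s["insulation"])
print("boundary violation change:", s["boundary_violation_change"])
print("pileup KO/WT ratios:", json.dumps(s["pileup_ko_wt_ratio"], indent=1))
print("distance rank-sum p:", s["distance_rank_sum_p"])
print(f"wrote {len(files)} report files to scratch_report/")
# Reading the summary: strength drops in KO, mid-range (0.5-5 Mb) contacts
# rise while >5 Mb contacts fall, inter-TAD contacts increase at every
# separation, disrupted-loop pileups collapse, and insulation-gain sites
# sit significantly closer to derepressed Polycomb genes than to any
# other gene class.
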