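"""End-to-end run: simulate -> QC -> stats -> ROH -> ancestry -> dating ->
outlier panels, via the config-driven pipeline, printing the headline block
of the machine-readable report.
"""

import json

from admixbreed.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=7))
s = report["stages"]

print("QC cascade           :", {k: v["sites"] for k, v in s["qc"].items()
                                 if isinstance(v, dict) and "sites" in v})
print("H_o by group         :", {k: round(v, 3) for k, v in s["stats"]["H_o"].items()})
print("F_ST matrix          :", json.dumps(
    {a: {b: round(v, 3) for b, v in row.items()}
     for a, row in s["stats"]["fst_matrix"].items()}))
print("F_ROH means          :", {k: round(v, 3)
                                 for k, v in s["roh"]["froh_mean"].items()})
print("wolf ancestry q      :", round(s["ancestry"]["mean_q_blocks"], 3),
      "(pedigree expectation", round(s["ancestry"]["mean_pedigree_expected_q"], 3),
      ", truth", round(s["ancestry"]["mean_truth_q"], 3), ")")
print("weighted-LD dating   :", round(s["dating"]["weighted_ld_generations"], 1),
      "generations ->", s["dating"]["weighted_ld_years"])
print("switch dating median :", round(s["dating"]["switch_dating_median"], 1),
      "generations (truth", s["dating"]["generations_since_last_admixture_truth"], ")")
print("outlier regions      :", s["outliers"])
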