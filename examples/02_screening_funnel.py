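"""Run the three-gate exclusion funnel on a synthetic cohort.

The funnel removes records with missing items, then any participant carrying
a confounding-comorbidity flag (nine closed categories), then totals below
the 9-point threshold, and reports the counts at every gate.
"""

import json

from sarcostage import SimConfig, generate_cohort, run_funnel

cohort = generate_cohort(SimConfig(n_total=1728, seed=42))
report = run_funnel(cohort)

d = report.to_dict()
breakdown = d.pop("comorbidity_breakdown")
print(json.dumps(d, indent=2))
print("largest excluded categories:")
for cat, counts in sorted(breakdown.items(), key=lambda kv: -sum(kv[1].values()))[:3]:
    print(f"  {cat}: {sum(counts.values())}")
# n_surveyed - missing - comorbid - below-threshold = n_final, the cohort
# eligible for stage assignment and intervention grading.
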