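"""Grade one participant: stage, dynamic weights, ratings, intervention tier.

The stage fixes the dimension weights (physiological falls 70% -> 55% from
stage A to D while psychological rises 20% -> 35%; external stays at 10%);
each of the 14 leaf indicators is rated 1-4 from a clinical instrument and
the weighted sum maps to Grade I (< 2), II (2-3.2) or III (> 3.2).
"""

from sarcostage import (
    InstrumentPanel,
    assign_stage,
    compose_stage_weights,
    intervention_score,
    rate_indicators,
    score_items,
    ses_score,
)

responses = [2, 2, 1, 2, 2, 2, 1, 2, 2, 1, 2, 2]  # total 21: High Risk band
banded = score_items(responses)
stage = assign_stage(banded, adl_independence=80)  # partial assistance -> C
ses = ses_score(income_band=2, education_band=2, occupation_band=1)

panel = InstrumentPanel(sarcf=5, adl_independence=80, fesi=33, hads=16,
                        gses=21, ses_total=ses.total)
ratings = rate_indicators(panel, stage)
result = intervention_score(ratings, compose_stage_weights(stage=stage))

print(f"questionnaire total : {banded.total} ({banded.band.label})")
print(f"stage               : {stage.name} ({stage.phase_name})")
print(f"SES                 : total {ses.total} -> {ses.group.value}")
print(f"intervention score  : {result.total_score:.3f}")
print(f"intervention grade  : {result.grade.value}")
# A decompensation-stage participant with moderate instrument scores lands
# in Grade II: structured intervention against accelerating decline.
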