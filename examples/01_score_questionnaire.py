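"""Score a 12-item self-assessment and read off the risk band.

Each item is answered 0 (no difficulty) to 3 (needs help); the 0-36 total
maps to Healthy (0-8), Pre-Sarcopenia Compensation (9-16), High Risk
(17-24) or Disabling Degeneration (>= 25).
"""

from sarcostage import score_items

# a respondent who needs rails on stairs, both hands for the oil bottle,
# rests while hanging laundry, but is otherwise independent
responses = [1, 1, 0, 1, 1, 2, 1, 1, 1, 0, 1, 1]

result = score_items(responses)
print(f"total score : {result.total}")
print(f"risk band   : {result.band.label}")
# A total of 11 lands in the 9-16 band: early compensation-stage decline,
# above the 9-point threshold for sarcopenia-specific assessment.
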