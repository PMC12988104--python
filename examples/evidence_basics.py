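"""Evaluate a concept from believed and social evidence, then revise.

An agent holding two belief items (attachments 1.0 and 0.5) judges a
proposed activity that fits the first item perfectly and the second one
half-way, while its single peer (full trust) approves the activity at 0.6.
The normalized believed-social evidence multiplies the two weighted means.
The revision rule then merges two observations of differing confidence
into one consolidated strength, under both evidence-weight conventions.
"""

from socev import Convention, Observation, normalized_evidence, revision

estimate = normalized_evidence(
    believed=[(1.0, 1.0), (0.5, 0.5)],  # (compatibility, attachment)
    social=[(0.6, 1.0)],  # (peer approval, trust)
)
print(f"normalized believed-social evidence: {estimate.normalized:.4f}")
# 0.5 = (1.25/1.5 believed mean) * (0.6 social mean): moderate support.

obs = [(0.9, 0.8), (0.5, 0.4)]  # (strength, confidence)
for convention in (Convention.STRENGTH, Convention.FREQUENCY_ODDS):
    merged = revision([Observation(f, c, convention) for f, c in obs])
    print(f"revised strength ({convention.value}): {merged:.4f}")
# The odds convention weights the confident observation more heavily,
# pulling the consolidated strength toward 0.9.
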