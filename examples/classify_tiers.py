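"""Assign risk tiers from two eGFR values plus code flags.

The tier logic: both eGFRs < 30 -> high risk; index < 30 with prior 30-60
-> intermediate (unless an AKI code appeared in the 90 days before the
index value); the mirror-image rising pattern and the both->=30 pattern
require an advanced-CKD diagnosis code; anything else is unclassified.
"""

from advckd import classify

cases = [
    (25.0, 28.0, False, False),  # persistently < 30
    (25.0, 45.0, False, False),  # newly < 30
    (25.0, 45.0, False, True),   # newly < 30 but AKI-coded -> carve-out
    (40.0, 25.0, True, False),   # recovered above 30, coded
    (40.0, 45.0, True, False),   # coded but never < 30
    (25.0, None, False, False),  # missing the confirmatory prior value
]
for index, prior, code, aki in cases:
    a = classify(index, prior, code, aki)
    sub = f" (subgroup {a.subgroup})" if a.subgroup else ""
    print(f"index={index:>5} prior={str(prior):>5} code={code!s:5} aki={aki!s:5}"
          f" -> {a.tier.value}{sub}")
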