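"""Compute MDRD eGFR from creatinine and demographics, and invert it.

The 4-variable MDRD equation estimates glomerular filtration rate from
serum creatinine, age, sex and race; values below 30 ml/min/1.73 m^2
correspond to advanced (stage 4-5) CKD.
"""

from advckd import compute_egfr_mdrd, invert_mdrd

egfr = compute_egfr_mdrd(creatinine_mg_dl=2.5, age_years=60, sex="male", race_black=False)
print(f"creatinine 2.5 mg/dL, 60 y male, non-Black -> eGFR {egfr:.1f} ml/min/1.73m^2")

female = compute_egfr_mdrd(2.5, 60, "female", False)
print(f"same labs, female                          -> eGFR {female:.1f} (x0.742)")

# the inverse is what the synthetic generator uses: pick a target eGFR,
# derive the creatinine a lab would have to report
cr = invert_mdrd(target_egfr=29.9, age_years=75)
print(f"eGFR 29.9 at 75 y male corresponds to creatinine {cr:.3f} mg/dL")
print(f"round trip: {compute_egfr_mdrd(cr, 75):.4f} (should be 29.9000)")
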