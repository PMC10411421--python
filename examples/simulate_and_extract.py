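"""Generate a synthetic registry and extract the advanced-CKD source cohort.

The generator emulates a health system where ~1.5% of creatinine-tested
enrollees have advanced CKD; the cohort build mirrors the selection flow:
active users -> tested users -> (eGFR arm OR diagnosis-code arm) minus
dialysis-coded patients.
"""

from advckd import GeneratorConfig, RunConfig, generate_registry, run_pipeline

registry = generate_registry(GeneratorConfig(n_patients=10_000, seed=42))
bundle = run_pipeline(RunConfig(), registry=registry)

print("cohort flow:", bundle["flow"].counts())
print("\ntier counts:", bundle["assignments"]["tier"].value_counts().to_dict())
ev = bundle["evidence"]
print(f"\nqualified via eGFR arm: {int(ev['egfr_arm'].sum())}, "
      f"via code arm: {int(ev['code_arm'].sum())}, "
      f"excluded by dialysis codes: {int(ev['excluded_dialysis'].sum())}")
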