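"""Six-month stability of each phenotype group on synthetic data.

pct_remaining is the probability that a patient's latest follow-up eGFR is
still below 30 ml/min/1.73 m^2 — i.e. that the phenotype's advanced-CKD
call was durable. The tiered phenotype grades this cleanly:
high > intermediate > low.
"""

from advckd import GeneratorConfig, RunConfig, generate_registry, run_pipeline

registry = generate_registry(GeneratorConfig(n_patients=20_000, seed=11))
bundle = run_pipeline(RunConfig(), registry=registry)

cols = ["n_group", "n_subsequent", "pct_any_ge30", "pct_current_ge30", "pct_remaining"]
print(bundle["stability"][cols].round(1).to_string())
print("\nmean/SD days between the stage-defining eGFR values:")
print(bundle["gap_stats"].round(1).to_string())
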