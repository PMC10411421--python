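import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from advckd import (
    GeneratorConfig,
    RegistryPaths,
    RunConfig,
    default_code_sets,
    generate_registry,
    match_codes,
    run_pipeline,
    truth_table,
    write_registry,
)
from advckd.egfr import lookback_start


def noiseless_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_patients=800, seed=2, w_high=0.45, w_intermediate=0.25, w_low=0.15,
        w_dialysis=0.0, frac_tested=1.0, creatinine_noise_sd=0.0,
        drift_per_month={g: 0.0 for g in ("high", "intermediate", "low", "non_ckd", "dialysis")},
        coding_sensitivity=1.0, coding_fp_rate=0.0, aki_rate=0.0,
        non_ckd_aki_rate=0.0, prior_available_prob=1.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def test_same_seed_same_bytes(tmp_path):
    cfg = GeneratorConfig(n_patients=250, seed=99)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        write_registry(generate_registry(cfg), RegistryPaths.in_dir(d), horizon_days=545)
    for name in ("patients", "labs", "diagnoses", "procedures"):
        assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()


def test_different_seed_different_output():
    r1 = generate_registry(GeneratorConfig(n_patients=250, seed=1))
    r2 = generate_registry(GeneratorConfig(n_patients=250, seed=2))
    assert not r1.equals(r2)


def test_generated_registry_passes_validation():
    reg = generate_registry(GeneratorConfig(n_patients=300, seed=6))
    assert reg.validate(horizon_days=365 + 180) == []


def test_zero_coding_sensitivity_selects_nobody_by_codes():
    cfg = GeneratorConfig(
        n_patients=1000, seed=3, coding_sensitivity=0.0,
        coding_sensitivity_code_defined=0.0, coding_fp_rate=0.0,
    )
    reg = generate_registry(cfg)
    window = (lookback_start(reg.reference_date).date(), reg.reference_date)
    coded = match_codes(
        reg.diagnoses.assign(system="ICD10"), default_code_sets()["advanced_ckd"], window
    )
    assert coded == set()


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(creatinine_noise_sd=-0.1).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(w_high=0.9, w_intermediate=0.2).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(coding_sensitivity=1.5).validate()
    with pytest.raises(ValueError):
        generate_registry(GeneratorConfig(n_patients=0))


def test_truth_table_structure_and_construction_flags():
    cfg = GeneratorConfig(n_patients=1500, seed=10, w_dialysis=0.05,
                          dialysis_miscoded_frac=0.6)
    reg = generate_registry(cfg)
    truth = truth_table(reg)
    assert len(truth) == 1500
    dial = truth[truth["dialysis"]]
    assert len(dial) > 0
    miscoded = dial[dial["miscoded_dialysis"]]
    # miscoded dialysis patients carry no dialysis codes, yet truth knows
    assert (~miscoded["dialysis_coded"]).all()
    assert (truth.loc[truth["group"] == "non_ckd", "true_tier"] == "none").all()
    # tier groups stay inside their defining true-eGFR ranges
    hi = truth[truth["true_tier"] == "high"].dropna(subset=["true_index_egfr"])
    assert (hi["true_index_egfr"] < 30).all() and (hi["true_prior_egfr"] < 30).all()
    lo = truth[truth["true_tier"] == "low"].dropna(subset=["true_index_egfr"])
    assert (lo["true_index_egfr"] >= 30).all() and (lo["true_prior_egfr"] >= 30).all()


def test_truth_table_requires_generated_registry(toy_registry):
    with pytest.raises(ValueError, match="ground truth"):
        truth_table(toy_registry)


def test_noiseless_limit_assigns_true_tiers_exactly():
    reg = generate_registry(noiseless_config())
    bundle = run_pipeline(RunConfig(), registry=reg)
    truth = truth_table(reg).set_index("patient_id")
    asg = bundle["assignments"].set_index("patient_id")
    adv = truth[truth["true_tier"] != "none"]
    assert adv.index.isin(asg.index).all()
    merged = adv.join(asg["tier"])
    assert (merged["tier"] == merged["true_tier"]).all()


def test_monte_carlo_sensitivity_matches_seminalytic_oracle():
    """Measured-index-below-30 rate vs the lognormal-noise closed form.

    With multiplicative creatinine noise exp(sigma*Z), measured eGFR is
    g*exp(-1.154*sigma*Z), so P(measured < 30 | true g) =
    Phi(ln(30/g) / (1.154*sigma)).  The single-eGFR phenotype's sensitivity
    against truth (true index < 30) must match the oracle's average.
    """
    sigma = 0.12
    cfg = GeneratorConfig(n_patients=5000, seed=31, w_high=0.5, w_intermediate=0.3,
                          w_low=0.1, w_dialysis=0.0, frac_tested=1.0,
                          creatinine_noise_sd=sigma, aki_rate=0.0, non_ckd_aki_rate=0.0,
                          extra_labs_rate=0.0)
    reg = generate_registry(cfg)
    bundle = run_pipeline(RunConfig(), registry=reg)
    truth = truth_table(reg).set_index("patient_id")
    labels = bundle["phenotype_labels"]
    pos_truth = truth[(truth["true_index_egfr"] < 30)].index
    pos_truth = pos_truth.intersection(labels.index)
    measured_pos = labels.loc[pos_truth, "single_egfr"].fillna(False).astype(bool)
    sg = 1.154 * sigma
    g = truth.loc[pos_truth, "true_index_egfr"].to_numpy(float)
    expected = norm.cdf(np.log(30.0 / g) / sg).mean()
    se = np.sqrt(expected * (1 - expected) / len(pos_truth))
    assert abs(measured_pos.mean() - expected) < 4 * se + 0.01


def test_configured_mixture_recovered_in_truth():
    cfg = GeneratorConfig(n_patients=4000, seed=12, w_high=0.3, w_intermediate=0.2,
                          w_low=0.1, w_dialysis=0.05)
    truth = truth_table(generate_registry(cfg))
    frac = truth["group"].value_counts(normalize=True)
    for g, w in (("high", 0.3), ("intermediate", 0.2), ("low", 0.1), ("dialysis", 0.05)):
        assert abs(frac[g] - w) < 3 * np.sqrt(w * (1 - w) / 4000)


def test_seed_override_argument():
    cfg = GeneratorConfig(n_patients=100, seed=1)
    assert generate_registry(cfg, seed=7).equals(
        generate_registry(dataclasses.replace(cfg, seed=7))
    )
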