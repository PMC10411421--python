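# Methods

## The phenotype

`advckd` implements a rule-based ("computable") EHR phenotype for advanced
nondialysis chronic kidney disease, defined over four tables: patients,
serum-creatinine laboratories, ICD-10 diagnoses and CPT procedures, all
relative to an extraction reference date.

**eGFR.** Kidney function is estimated with the 4-variable IDMS-traceable
MDRD equation (coefficient 175, creatinine exponent −1.154, age exponent
−0.203, ×0.742 for women, ×1.212 for Black patients). The coefficient is
configurable (`coefficient=` on `compute_egfr_mdrd`/`add_egfr`) because
older deployments used the 186 re-expression. Age is evaluated at each
lab's collection date — from `birth_date` when available, otherwise by
shifting `age_years` (age at the reference date) by the elapsed time.
CKD-EPI and cystatin-C equations, unit conversion from µmol/L, and
albuminuria staging are deliberately out of scope. `invert_mdrd` solves the
equation for creatinine; it exists so the synthetic generator can plant
labs with known true eGFR, and is exact (the round trip is tested to 1e-9
relative tolerance).

**Index and prior values.** The index eGFR is the value with the latest
collection date inside the closed 365-day lookback window
[reference − 364 d, reference]; the prior eGFR is the latest value dated at
least 90 days before the index and still inside the window ("the most
recent confirmatory value", not the oldest). Same-day duplicates resolve to
the lowest eGFR — the conservative choice for a screen whose positives are
low values; this tie-break is a documented substitute for an unstated
convention, and both the 365-day and 90-day windows are parameters.
Thresholds always compare full-precision values; nothing is rounded before
classification.

**Cohort and tiers.** The source cohort is (index eGFR ≤ 30) OR
(N18.4/N18.5 code in the lookback), minus anyone matched by the dialysis
code set. Two deliberate asymmetries are preserved rather than harmonized,
with switches: the cohort's eGFR arm is inclusive (≤ 30) while every tier
rule compares strictly (< 30) (`cohort_egfr_inclusive`); and the
advanced-CKD-code requirement applies to intermediate subgroup 2 and low
but not to subgroup 1. The AKI carve-out removes from subgroup 1 (only)
patients with an N17-prefixed code in the closed 90-day window before their
index date. Combinations the tier table does not define — index < 30 with
prior ≥ 60, index ≥ 60 with prior < 30 and no code, missing prior — are
labeled `unclassified` instead of being forced into a tier, so the tiers
remain mutually exclusive and collectively exhaustive over the cohort.
Code-arm members with no usable eGFR are kept in the cohort but flagged
unclassifiable by eGFR.

**Code matching.** ICD-10 codes are dot-normalized and matched by prefix
("N17" covers N17.0…N17.9; "N184" ≡ "N18.4"), CPT codes exactly; both over
closed date windows. The shipped dialysis/ESKD exclusion list (ICD-10
N18.6, Z99.2, Z49.*; CPT 90935–90999) is a clearly-labeled stand-in —
institutional dialysis lists vary — and is overridable via a YAML code-set
file.

**Evaluation.** Prevalence uses the creatinine-tested population as its
denominator (patients who never get labs cannot contribute an eGFR, so
including them understates disease burden). Binomial CIs are Wilson score
by default with Wald as an option; at cohort-scale denominators both round
to the same one-decimal bounds, and display rounding is half-up (ties away
from zero), the convention clinical tables use. Diagnostic accuracy
cross-tabulates code-positivity against each eGFR-based reference standard
over the tested universe; a metric with a zero denominator is reported as
undefined, never 0. Six-month stability counts, per group: patients with
any follow-up eGFR (dated after their index, within a 180-day horizon) —
the "any ≥ 30" row is a percent of the whole group, while "current ≥ 30"
(the latest in-horizon value) is a percent of those with a follow-up
measurement; `pct_remaining` is its complement. The two rows intentionally
have different denominators, so no ordering between them is asserted.
Cumulative 6-month prevalence re-runs the extraction at monthly snapshot
dates and takes the union of ever-high/intermediate patients over the fixed
baseline tested denominator.

## The synthetic generator

`generate_registry` emulates the data-generating process the phenotype
assumes, with ground truth attached for scoring. Per patient: a mixture
group (high / intermediate / low / non-CKD / dialysis), demographics
(age ~ truncated normal 75.3 ± 11.1 on [20, 105], 95.8% male, 21.9% Black,
67.8% white — an elderly, male-dominated clinical population), and a true
eGFR trajectory: stage-defining index and prior values drawn from truncated
normals inside each tier's defining range (high 20.3 ± 6.6, intermediate
index 27.4 ± 5.6 with prior 45 ± 10, low 42.1 ± 16.6, non-CKD 78 ± 18,
dialysis 8 ± 3 ml/min/1.73 m²), flat history before the prior, linear
group-specific drift after the index (−0.2 to −0.3 /month for declining
groups). Creatinine is derived by inverting the MDRD equation at the true
value and multiplied by lognormal noise.

Default conditions approximate a regional health system: advanced CKD
~1.5% of tested users (weights 0.69% high, 0.36% intermediate, 0.24% low of
all enrollees), 69% of non-CKD enrollees creatinine-tested (risk groups are
always tested), 98% of advanced patients with a usable prior value, 8% of
intermediates following the rising subgroup-2 pattern, follow-up
measurement coverage of 50–60% by group, and a stage-defining gap drawn
uniformly on 95–300 days. Coding: code-defined groups (low, subgroup 2)
carry advanced-CKD codes with probability 1.0 by default (they can only be
recognized through codes), eGFR-defined groups with sensitivity 0.55 —
which reproduces the 55–65% code sensitivity regime seen in real systems —
plus a 3·10⁻⁴ false-positive rate; dialysis patients carry dialysis codes
unless "miscoded" (default 50%), the contamination a manual chart review
would catch. AKI episodes (3% of subgroup-1 intermediates, 1% of non-CKD)
plant an N17 code and a transient creatinine spike inside the 90 days
before the index.

**Noise calibration.** The creatinine noise SD is 0.12 (CV ≈ 12%),
representing combined biological and analytical intra-individual
variability. Pure multiplicative noise reproduces only part of the
regression-above-30 observed in real repeat measurements of stage-4
patients (the rest reflects genuine clinical fluctuation — AKI recovery,
volume shifts — which the generator carries separately as AKI shock
events); the resulting follow-up behavior nonetheless grades exactly as the
tiering predicts (see below).

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: regression to the mean from baseline
selection (groups are conditioned on *true* stage, so the intermediate
tier's real-world instability is understated), co-morbidity-correlated
coding, inpatient/outpatient measurement differences, assay changes over
time, and care-seeking behavior correlated with disease severity beyond the
group-wise lab-rate differences. The stability ordering
(high > intermediate > low) and parameter-recovery results are structural
properties of the rules, not estimates of real-world operating
characteristics.

## Numerical choices and problem sizes

Seeds fix every draw (`numpy.random.default_rng`); the full
generate → extract → classify → evaluate pipeline is byte-reproducible.
Degenerate inputs: empty registries validate and round-trip; empty groups
are omitted from stability reports with a warning; denominator-zero
proportions raise (prevalence) or report undefined (accuracy metrics);
missing index eGFR is a contract violation for `classify` but a normal
"absent" outcome for pair selection. Validation enumerates every failing
row and never mutates inputs.

The test suite exercises the oracle-equivalence battery on 200 random
registries of 30–130 patients (brute-force per-patient loops vs the pandas
implementations), parameter recovery on cohorts of 1,759–5,000 patients,
and the stability ordering on 20,000 enrollees; the acceptance script uses
20,000. These sizes give binomial sampling errors comfortably inside the
stated tolerances (e.g. ±3 percentage points for tier-mixture recovery at
n = 1,759) while keeping a full run in seconds.

## Known limitations

* The MDRD equation (including its race coefficient) is implemented for
  fidelity to the era's laboratory convention, not as a recommendation;
  current practice uses race-free CKD-EPI 2021.
* The dialysis exclusion list is a stand-in default and must be localized.
* Tier rules are cross-sectional on two values; no survival or trajectory
  modeling is attempted.
* `unclassified` is an honest residual, not a clinical judgment; in a
  deployment those patients need manual review.
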