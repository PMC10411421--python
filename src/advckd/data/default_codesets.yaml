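# Default code sets for advanced-CKD phenotyping.
#
# advanced_ckd and aki are the category definitions used by the phenotype
# (ICD-10 N18.4 / N18.5 for CKD stages 4-5, N17 for acute kidney injury;
# ICD-10 entries match by prefix, so "N17" covers N17.0, N17.1, ...).
#
# The dialysis/ESKD exclusion list below is a stand-in default: institutional
# dialysis code lists vary and should be supplied via your own YAML file with
# the same structure (load_code_sets). CPT entries may be single codes or
# closed numeric ranges like "90935-90999".
advanced_ckd:
  icd10: ["N18.4", "N18.5"]
aki:
  icd10: ["N17"]
dialysis:
  icd10: ["N18.6", "Z99.2", "Z49"]
  cpt: ["90935-90999"]
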