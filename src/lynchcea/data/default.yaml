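# Base-case configuration of the Lynch syndrome screening cost-effectiveness
# model (Italian National Health Service perspective, EUR, ages in years).
#
# Provenance tags (bottom of file):
#   printed                   -- stated in the main text of the source study
#   supplementary_placeholder -- lives in supplementary material we do not
#                                assert; plausible default, override freely
#   assumption                -- modelling assumption

# ---- proband cohort epidemiology ------------------------------------------
incident_crc_cases: 49000        # newly diagnosed CRC cases per year, Italy
crc_incidence_rate: 0.0009       # informational (0.09%)
ls_share: 0.0281                 # share of CRC probands with Lynch syndrome
prop_age_ge70: 0.40              # share of CRC probands diagnosed at >= 70 y
sex_split: 0.5                   # proportion female among FDR carriers

# ---- diagnostic test performance ------------------------------------------
test_performance:
  ihc:
    sensitivity: 0.83
    specificity: 0.89
    unit_cost: 120.0
  ms_mlpa:                       # methylation-specific MLPA on MLH1-absent tumors
    sensitivity: 0.98            # detects promoter methylation when present
    specificity: 0.98            # calls unmethylated tumors unmethylated
    unit_cost: 150.0
  bethesda:                      # revised Bethesda clinical criteria
    sensitivity: 0.78
    specificity: 0.77
    unit_cost: 0.0               # clinical checklist, no tariff item
  sequencing:                    # germline MMR sequencing (NGS)
    sensitivity: 1.0
    specificity: 1.0
    unit_cost: 250.0             # implied by strategy-1 totals / tested count
  fdr_predictive:                # targeted single-variant test in relatives
    sensitivity: 1.0
    specificity: 1.0
    unit_cost: 82.17             # implied by cascade cost per detected proband

gene_distribution:               # pathogenic-variant gene among LS probands
  MLH1: 0.40
  MSH2: 0.34
  MSH6: 0.18
  PMS2: 0.08
sporadic_mlh1_methylation_share: 0.10   # sporadic CRC with methylated MLH1 loss

# ---- uptake and family structure ------------------------------------------
uptake_proband: 0.848
uptake_fdr: 0.389
n_fdr_per_proband: 3.0
p_fdr_carrier: 0.5               # autosomal dominant transmission
fdr_entry_age: 25

adherence_colonoscopy: 0.80
surgery_acceptance: 0.19

# ---- natural history of carriers ------------------------------------------
cum_crc_risk_male: 0.38          # cumulative to age 70
cum_crc_risk_female: 0.31
crc_risk_window: [25, 70]
cum_ec_risk_female: 0.35
ec_risk_window: [25, 70]
stage_dist_surveilled: [0.694, 0.25, 0.056, 0.0004]   # renormalized in-model
stage_dist_unsurveilled: [0.267, 0.533, 0.133, 0.067]
stage_survival:                  # annual death probability, 5 post-dx years
  crc: {1: 0.03, 2: 0.08, 3: 0.18, 4: 0.45}
  ec_by_year: [0.08, 0.05, 0.03, 0.02, 0.01]
  second_cancer: 0.12
p_second_cancer: 0.02            # annual, after a first cancer
aspirin_rr_crc: 0.65             # relative risk on CRC incidence, 100 mg/day

background_mortality:            # Gompertz hazard a*exp(b*age) per sex
  male: {a: 2.7e-5, b: 0.095}
  female: {a: 1.4e-5, b: 0.098}

# ---- intervention schedules -----------------------------------------------
schedules:
  colonoscopy_interval_surveilled: 2.0
  colonoscopy_start_surveilled: 25
  gyn_surveillance_start: 35
  prophylactic_surgery_age: 45
  colonoscopy_interval_unsurveilled: 5.0
  colonoscopy_start_unsurveilled: 45

# ---- unit costs (EUR) ------------------------------------------------------
unit_costs:
  colonoscopy: 100.0
  gyn_visit_endometrial_sampling: 80.0
  transvaginal_ultrasound: 50.0
  prophylactic_surgery: 3000.0
  aspirin_year: 20.0
  crc_management: {1: 12000.0, 2: 20000.0, 3: 32000.0, 4: 42000.0}
  ec_management: 18000.0
  second_cancer_management: 30000.0
  post_cancer_followup: 500.0

# ---- utilities --------------------------------------------------------------
utilities:
  well: 1.0
  crc_by_stage: {1: 0.74, 2: 0.70, 3: 0.59, 4: 0.25}
  ec: 0.72
  second_cancer: 0.60
  alive_after_cancer: 0.95

# ---- economics ---------------------------------------------------------------
discount_rate: 0.035
wtp_threshold: 30000.0
max_age: 100
half_cycle_correction: false

# ---- provenance --------------------------------------------------------------
provenance:
  incident_crc_cases: printed
  crc_incidence_rate: printed
  ls_share: printed
  prop_age_ge70: supplementary_placeholder
  sex_split: assumption
  test_performance.ihc: supplementary_placeholder
  test_performance.ms_mlpa: supplementary_placeholder
  test_performance.bethesda: supplementary_placeholder
  test_performance.sequencing: supplementary_placeholder
  test_performance.fdr_predictive: printed   # sens/spec 100%; cost placeholder
  gene_distribution: supplementary_placeholder
  sporadic_mlh1_methylation_share: printed
  uptake_proband: printed
  uptake_fdr: printed
  n_fdr_per_proband: supplementary_placeholder
  p_fdr_carrier: assumption
  fdr_entry_age: supplementary_placeholder
  adherence_colonoscopy: printed
  surgery_acceptance: printed
  cum_crc_risk_male: printed
  cum_crc_risk_female: printed
  cum_ec_risk_female: printed
  crc_risk_window: assumption
  ec_risk_window: assumption
  stage_dist_surveilled: printed
  stage_dist_unsurveilled: printed
  stage_survival: supplementary_placeholder
  p_second_cancer: supplementary_placeholder
  aspirin_rr_crc: supplementary_placeholder
  background_mortality: assumption
  schedules: printed
  unit_costs: supplementary_placeholder
  utilities: supplementary_placeholder
  utilities.alive_after_cancer: printed
  discount_rate: printed
  wtp_threshold: printed
  max_age: assumption
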