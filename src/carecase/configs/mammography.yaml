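# Base-case parameters for the five-year breast-cancer screening model
# (employed African-American women aged 50-65).  Sources: the published
# input-parameter table and its appendix; fields marked "package default"
# are documented modelling assumptions where the source gives no value.
kind: mammography

# --- state transition probabilities -----------------------------------------
# SEER-range annual incidence for the 50-65 age band (reference value).
annual_incidence_base: 0.003
# Cancers found per woman-cycle.  annual/biennial/sporadic entries are
# per-mammogram detection probabilities in screened cycles ("3 cancers per
# 1,000 mammograms", 5/1,000 for sporadic screeners); the "none" entry is the
# clinical-detection probability in any cycle without a mammogram (8/1,000).
incidence_by_pattern:
  annual: 0.003
  biennial: 0.003
  sporadic: 0.005
  none: 0.008
# Stage at diagnosis, screened cycles: annual/biennial use the
# Jacobellis-Cutter distribution, sporadic the Yood managed-care distribution.
stage_dist_screened:
  annual:
    probabilities: {in_situ: 0.13, I: 0.41, II: 0.37, III: 0.07, IV: 0.02}
    provenance_label: screened annual (Jacobellis-Cutter)
  biennial:
    probabilities: {in_situ: 0.13, I: 0.41, II: 0.37, III: 0.07, IV: 0.02}
    provenance_label: screened biennial (Jacobellis-Cutter)
  sporadic:
    probabilities: {in_situ: 0.17, I: 0.29, II: 0.40, III: 0.09, IV: 0.05}
    provenance_label: screened sporadic (Yood)
# Stage at diagnosis without a mammogram that year (clinical detection).
stage_dist_unscreened:
  probabilities: {in_situ: 0.04, I: 0.32, II: 0.43, III: 0.13, IV: 0.08}
  provenance_label: unscreened / clinical detection
remission_in_diagnosis_year_by_stage: {I: 0.975, II: 0.94, III: 0.81, IV: 0.66}
continued_remission_by_stage: {I: 0.975, II: 0.94, III: 0.81, IV: 0.66}
# Annual cancer death rates by stage imposed on the remission dynamics
# (years 2-5) through the recurrence -> death branch.
annual_cancer_death_rate_by_stage: {I: 0.0075, II: 0.03, III: 0.126, IV: 0.264}
# Death probability given progressive/recurrent disease (diagnosis-year
# non-remission branch and the progressive state).
death_given_progression: 0.79
other_cause_death_annual: 0.01

# --- utilities ----------------------------------------------------------------
utility_well: 1.0
utility_newly_diagnosed_by_stage: {I: 0.90, II: 0.85, III: 0.81, IV: 0.81}
treatment_disutility_by_stage: {I: -0.10, II: -0.20, III: -0.25, IV: -0.25}
utility_progressive: 0.40

# --- employment ---------------------------------------------------------------
employment_prob_well: 1.0  # cohort assumed employed at baseline
employment_treatment_year_by_stage: {in_situ: 0.86, I: 0.70, II: 0.60, III: 0.50, IV: 0.40}
employment_remission_by_stage: {I: 0.94, II: 0.88, III: 0.81, IV: 0.75}
employment_progressive: 0.56

# --- costs (USD) --------------------------------------------------------------
treatment_cost_by_stage: {I: 22488.0, II: 27213.0, III: 29220.0, IV: 31476.0}
cost_recurrent: 33000.0
cost_in_situ_treatment: 0.0      # no published in-situ cost; package default
cost_mammogram: 81.86            # Federal Register, 2007
cost_false_positive_followup: 533.0
false_positive_rate: 0.10        # fraction of mammograms read as suspicious
false_positive_rescreen_boost: 0.10  # relative screening increase after a false positive

# --- absenteeism --------------------------------------------------------------
days_missed_treatment_year_mean: 44.5
# Per-stage treatment-year missed days, rising with stage; chosen so the
# expectation under the base-case stage-at-diagnosis mix is ~44.5 days
# (package default split; only the mean is published).
days_missed_by_stage: {in_situ: 11.0, I: 34.0, II: 46.0, III: 69.0, IV: 92.0}
days_missed_progressive_year: 92.0  # package default: stage-IV level

# --- run controls ---------------------------------------------------------------
horizon_years: 5
death_cycle_fraction: 0.5  # part-year utility accrual in the year of death
discount_rate: 0.0         # no discounting in the published analysis
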