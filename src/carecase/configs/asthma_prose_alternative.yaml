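# Alternative asthma parameterization using the methods-prose values where
# they differ from the canonical input table: restart probability after an
# office-visit exacerbation 0.15 (vs 0.25) and days missed 4/5/7 per month
# for exacerbation / ER / admission (vs 3/4/7).  Shipped as a named config
# so the discrepancy between the two published sets can be explored.
kind: asthma

med_use_rate: 0.80

p_exac_no_er: {with_med: 0.27, without_med: 0.53}
p_exac_er: {with_med: 0.0382, without_med: 0.0756}
p_exac_admit: {with_med: 0.0035, without_med: 0.0069}

persistence:
  "on": {none: 0.96, exac: 0.96, er: 0.99, admit: 0.99}
  "off": {none: 0.01, exac: 0.15, er: 0.25, admit: 0.25}
persistence_presets:
  0.80:
    "on": {none: 0.96, exac: 0.96, er: 0.99, admit: 0.99}
    "off": {none: 0.01, exac: 0.15, er: 0.25, admit: 0.25}

p_death_er: 0.0002
p_death_admit: 0.0014
p_death_other_monthly: 0.0001

utilities_monthly:
  none: {with_med: 0.0748, without_med: 0.0756}
  exac: {with_med: 0.0706, without_med: 0.0712}
  er: {with_med: 0.0698, without_med: 0.0704}
  admit: {with_med: 0.0649, without_med: 0.0654}
daily_utilities:
  normal_no_med: 0.92
  normal_med: 0.91
  exac_day: 0.72
  er_extra_decrement: 0.05
  admit_extra_decrement: 0.10
  med_disutility: 0.01

days_available_per_month: {adult: 21.67, child: 15.0}
days_missed: {exac: 4.0, er: 5.0, admit: 7.0}
costs: {office_visit: 155.44, er: 1080.0, admission: 13512.0, med_monthly: 112.0}

horizon_months: 60
parent_workday_ratio: 1.0
death_cycle_fraction: 0.5
discount_rate: 0.0
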