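# Employer-perspective economic assumptions.
kind: economics

hourly_wage: 21.31      # average hourly wage, US Department of Labor, May 2007
hours_per_day: 8.0
hours_per_year: 2080.0
turnover_fraction: 0.33 # replacement cost as a fraction of annual salary
currency_rounding: 2
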