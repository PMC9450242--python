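id,expected,tolerance
total_sud_prevalence_pct,14.6,0.1
alcohol_sud_prevalence_pct,13.0,0.5
any_psychiatric_prevalence_pct,26.7,0.1
sud_psychiatric_comorbidity_pct,4.8,0.1
boys_sud_with_psychiatric_pct,22.0,0.5
boys_psychiatric_with_sud_pct,15.0,0.5
girls_sud_with_psychiatric_pct,40.0,0.5
gambling_at_risk_prevalence_pct,5.2,0.1
gambling_problem_prevalence_pct,1.7,0.1
gambling_pathological_prevalence_pct,1.4,0.1
gaming_at_risk_prevalence_pct,3.0,0.1
boys_gambling_disorder_pct,5.8,0.1
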