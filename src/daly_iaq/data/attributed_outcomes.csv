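hazard,outcome,incidence,incidence_lo,incidence_hi,daly_per_case,daly_lo,daly_hi,rate_basis
SHS,asthma_episodes,202300,,,0.040,,,national_count
SHS,otitis_media_visits,790000,,,0.022,,,national_count
SHS,sudden_infant_death_syndrome,430,,,78,,,national_count
SHS,cardiac_death,46000,22700,69600,1,,,national_count
SHS,lung_cancer_death,3400,,,14,,,national_count
radon_smoker,lung_cancer_death,18000,5600,58000,14,,,national_count
radon_nonsmoker,lung_cancer_death,3000,950,96000,14,,,national_count
acute_CO,poisoning_death,1.53,1.47,1.59,32,,,per_million_rate
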