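pollutant,outcome,beta,beta_lo,beta_hi,y0,form,daly,daly_lo,daly_hi
PM2.5,total_mortality,0.058,0.002,0.010,7.4e-3,exponential,1.4,0.14,14
PM2.5,chronic_bronchitis,0.091,0.078,0.105,4.0e-4,exponential,1.2,0.12,12
PM2.5,nonfatal_stroke,0.025,0.002,0.048,2.0e-4,exponential,,,
CO,hospital_admissions_asthma,0.033,0.016,0.050,1.8e-3,exponential,4e-4,4e-4,4e-4
CO,hospital_admissions_lung_disease,0.025,0.000,0.057,2.1e-3,exponential,4e-4,4e-4,4e-4
CO,hospital_admissions_dysrhythmias,0.058,0.012,0.102,2.4e-3,exponential,4e-4,4e-4,4e-4
CO,hospital_admissions_heart_failure,0.034,0.002,0.066,3.4e-3,exponential,4e-4,4e-4,4e-4
NO2,hospital_admissions_respiratory,0.004,0.000,0.008,9.5e-3,exponential,4e-4,4e-4,4e-4
NO2,hospital_admissions_congestive_heart_failure,0.003,0.001,0.004,3.4e-3,exponential,4e-4,4e-4,4e-4
NO2,hospital_admissions_ischemic_heart_disease,0.003,0.002,0.004,8.0e-3,exponential,4e-4,4e-4,4e-4
NO2,respiratory_illness_symptoms,0.028,0.002,0.053,,linearized,4e-4,4e-4,4e-4
Ozone,mortality,0.001,0.000,0.002,7.7e-3,exponential,1.0,0.1,10
Ozone,hospital_admissions_asthma,0.003,0.001,0.004,1.8e-3,exponential,4e-4,4e-4,4e-4
Ozone,hospital_admissions_lung_disease,0.003,0.001,0.005,2.1e-3,exponential,4e-4,4e-4,4e-4
Ozone,hospital_admissions_respiratory_infection,0.002,0.001,0.003,5.8e-3,exponential,4e-4,4e-4,4e-4
Ozone,hospital_admissions_dysrhythmias,0.002,0.000,0.004,2.4e-3,exponential,4e-4,4e-4,4e-4
SO2,hospital_admissions,0.002,0.000,0.003,8.0e-3,exponential,4e-4,4e-4,4e-4
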