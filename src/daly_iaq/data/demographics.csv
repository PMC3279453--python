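label,population_fraction,adaf,time_at_home,intake_m3_day
under_2,0.03,10,0.75,7
2_to_16,0.19,3,0.75,13
over_16,0.78,1,0.69,15
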