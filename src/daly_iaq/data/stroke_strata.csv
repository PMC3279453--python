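stratum,daly,daly_lo,daly_hi
0_complications,9.5,9.25,9.75
1_complication,11.7,11.1,12.4
gt1_complications,13.1,12.2,14.0
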