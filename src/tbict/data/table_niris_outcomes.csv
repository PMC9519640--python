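niris,n,dead_icu,dead_hospital,dead_6mo,gcs_3_8,gcs_9_12,gcs_13_15,age_median,age_q1,age_q3
0,320,9,19,27,104,52,164,38,26,54
1,225,2,6,12,77,37,111,43,25,57
2,1297,63,105,220,512,268,517,54,41,67
3,526,38,72,142,240,138,148,59,47,69
4,663,108,187,309,477,90,96,60,51,70
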