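nominal_ng_per_ml,mean_ng_per_ml,sd_ng_per_ml,recovery_percent
1.0,0.96,0.02,95.67
15.0,14.58,0.27,97.20
50.0,51.81,1.03,103.61
300.0,292.89,6.48,97.63
500.0,495.33,8.38,99.07
1500.0,1503.53,7.68,100.24
3000.0,3026.59,21.46,100.89
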