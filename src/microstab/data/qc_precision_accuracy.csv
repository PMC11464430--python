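scope,level_ng_per_ml,mean_ng_per_ml,sd_ng_per_ml
intra_day,1.0,0.96,0.02
intra_day,3.0,3.02,0.19
intra_day,900.0,912.54,10.53
intra_day,2400.0,2388.17,3.79
inter_day,1.0,0.98,0.04
inter_day,3.0,3.10,0.03
inter_day,900.0,923.74,11.54
inter_day,2400.0,2404.06,9.14
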