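condition,level_ng_per_ml,mean_ng_per_ml,sd_ng_per_ml
long_term,3.0,2.95,0.03
long_term,2400.0,2394.79,1.43
auto_sampler,3.0,3.02,0.04
auto_sampler,2400.0,2411.88,13.39
short_term,3.0,3.02,0.10
short_term,2400.0,2394.87,9.37
freeze_thaw,3.0,2.90,0.05
freeze_thaw,2400.0,2389.56,3.29
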