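time_min,replicate,conc_ng_per_ml
0.0,1,466.85
2.5,1,425.67
5.0,1,400.46
7.5,1,366.10
15.0,1,305.41
20.0,1,248.27
30.0,1,174.84
40.0,1,117.41
50.0,1,101.54
70.0,1,100.05
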