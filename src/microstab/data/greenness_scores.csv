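criterion,score,weight
1,0.3,2
2,0.82,2
3,0.66,1
4,1.0,2
5,0.75,3
6,1.0,2
7,0.91,3
8,1.0,2
9,0.0,2
10,0.5,2
11,1.0,3
12,0.8,2
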