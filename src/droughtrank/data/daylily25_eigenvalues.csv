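component,eigenvalue
1,4.278
2,3.109
3,2.241
4,1.017
5,0.705
6,0.421
7,0.385
8,0.286
9,0.253
10,0.208
11,0.087
12,0.01
13,0.001
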