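genotype,mu1,mu2,mu3,D,rank
S1,0.658,0.474,0.861,0.478,2
S2,0.424,0.447,0.405,0.316,13
S3,0.380,0.429,0.355,0.289,17
S4,0.705,0.374,0.561,0.418,3
S5,0.531,0.367,0.185,0.294,16
S6,0.613,0.161,0.585,0.341,10
S7,0.397,0.505,0.271,0.298,15
S8,0.790,0.890,0.670,0.588,1
S9,0.505,0.481,0.272,0.328,11
S10,0.428,0.613,0.713,0.410,4
S11,0.062,0.901,0.742,0.364,8
S12,0.390,0.000,0.006,0.129,24
S13,0.087,0.484,0.518,0.234,20
S14,0.250,0.245,0.532,0.233,21
S15,0.711,0.286,0.379,0.368,7
S16,0.143,0.599,0.328,0.247,19
S17,0.433,0.438,0.562,0.344,9
S18,0.401,0.502,0.000,0.252,18
S19,0.654,0.091,1.000,0.409,5
S20,1.000,0.028,0.366,0.399,6
S21,0.316,0.361,0.205,0.226,22
S22,0.133,1.000,0.124,0.304,14
S23,0.000,0.226,0.123,0.075,25
S24,0.158,0.297,0.585,0.224,23
S25,0.279,0.524,0.575,0.316,12
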