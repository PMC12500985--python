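genotype,F1,F2,F3
S1,2.894,1.057,1.024
S2,1.997,0.985,-0.141
S3,1.827,0.935,-0.270
S4,3.075,0.787,0.257
S5,2.406,0.767,-0.705
S6,2.723,0.210,0.319
S7,1.894,1.141,-0.484
S8,3.403,2.182,0.535
S9,2.310,1.075,-0.481
S10,2.011,1.432,0.646
S11,0.606,2.212,0.720
S12,1.867,-0.225,-1.162
S13,0.701,1.083,0.148
S14,1.329,0.438,0.183
S15,3.098,0.549,-0.208
S16,0.917,1.394,-0.338
S17,2.030,0.959,0.260
S18,1.907,1.131,-1.178
S19,2.878,0.022,1.380
S20,4.209,-0.150,-0.241
S21,1.583,0.751,-0.652
S22,0.879,2.479,-0.861
S23,0.368,0.387,-0.863
S24,0.977,0.577,0.319
S25,1.442,1.193,0.293
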