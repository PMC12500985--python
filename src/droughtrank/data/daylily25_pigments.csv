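genotype,index,condition,mean,sd
S1,Chl,control,1.224,0.181
S1,Chl_a,control,0.898,0.139
S1,Chl_b,control,0.326,0.044
S1,Chl_a_b,control,2.749,0.149
S1,Car,control,0.560,0.046
S1,Chl,treatment,1.241,0.360
S1,Chl_a,treatment,0.926,0.278
S1,Chl_b,treatment,0.315,0.084
S1,Chl_a_b,treatment,2.913,0.172
S1,Car,treatment,0.593,0.119
S2,Chl,control,1.218,0.239
S2,Chl_a,control,0.887,0.174
S2,Chl_b,control,0.331,0.070
S2,Chl_a_b,control,2.696,0.276
S2,Car,control,0.477,0.129
S2,Chl,treatment,1.229,0.208
S2,Chl_a,treatment,0.892,0.308
S2,Chl_b,treatment,0.338,0.114
S2,Chl_a_b,treatment,2.676,0.403
S2,Car,treatment,0.516,0.173
S3,Chl,control,0.898,0.161
S3,Chl_a,control,0.670,0.121
S3,Chl_b,control,0.228,0.040
S3,Chl_a_b,control,2.930,0.103
S3,Car,control,0.297,0.047
S3,Chl,treatment,1.195,0.327
S3,Chl_a,treatment,0.883,0.230
S3,Chl_b,treatment,0.313,0.099
S3,Chl_a_b,treatment,2.863,0.183
S3,Car,treatment,0.507,0.233
S4,Chl,control,1.165,0.204
S4,Chl_a,control,0.863,0.153
S4,Chl_b,control,0.303,0.054
S4,Chl_a_b,control,2.855,0.167
S4,Car,control,0.589,0.046
S4,Chl,treatment,1.082,0.210
S4,Chl_a,treatment,0.794,0.170
S4,Chl_b,treatment,0.288,0.040
S4,Chl_a_b,treatment,2.733,0.233
S4,Car,treatment,0.649,0.054
S5,Chl,control,0.964,0.388
S5,Chl_a,control,0.701,0.289
S5,Chl_b,control,0.263,0.102
S5,Chl_a_b,control,2.672,0.292
S5,Car,control,0.340,0.114
S5,Chl,treatment,1.246,0.426
S5,Chl_a,treatment,0.927,0.324
S5,Chl_b,treatment,0.318,0.103
S5,Chl_a_b,treatment,2.902,0.145
S5,Car,treatment,0.480,0.090
S6,Chl,control,1.443,0.144
S6,Chl_a,control,1.070,0.121
S6,Chl_b,control,0.373,0.025
S6,Chl_a_b,control,2.865,0.170
S6,Car,control,0.541,0.041
S6,Chl,treatment,0.948,0.147
S6,Chl_a,treatment,0.714,0.109
S6,Chl_b,treatment,0.234,0.041
S6,Chl_a_b,treatment,3.070,0.254
S6,Car,treatment,0.577,0.113
S7,Chl,control,0.958,0.200
S7,Chl_a,control,0.705,0.136
S7,Chl_b,control,0.253,0.064
S7,Chl_a_b,control,2.825,0.210
S7,Car,control,0.590,0.093
S7,Chl,treatment,1.205,0.389
S7,Chl_a,treatment,0.892,0.308
S7,Chl_b,treatment,0.313,0.108
S7,Chl_a_b,treatment,2.869,0.107
S7,Car,treatment,0.703,0.070
S8,Chl,control,1.035,0.353
S8,Chl_a,control,0.777,0.273
S8,Chl_b,control,0.258,0.081
S8,Chl_a_b,control,2.973,0.176
S8,Car,control,0.642,0.145
S8,Chl,treatment,1.451,0.351
S8,Chl_a,treatment,1.071,0.271
S8,Chl_b,treatment,0.379,0.084
S8,Chl_a_b,treatment,2.815,0.210
S8,Car,treatment,0.849,0.091
S9,Chl,control,1.404,0.141
S9,Chl_a,control,1.217,0.294
S9,Chl_b,control,0.437,0.162
S9,Chl_a_b,control,2.871,0.319
S9,Car,control,0.583,0.049
S9,Chl,treatment,1.171,0.537
S9,Chl_a,treatment,0.884,0.397
S9,Chl_b,treatment,0.287,0.140
S9,Chl_a_b,treatment,3.124,0.228
S9,Car,treatment,0.641,0.030
S10,Chl,control,1.172,0.299
S10,Chl_a,control,0.871,0.222
S10,Chl_b,control,0.301,0.081
S10,Chl_a_b,control,2.908,0.290
S10,Car,control,0.485,0.067
S10,Chl,treatment,1.167,0.130
S10,Chl_a,treatment,0.856,0.102
S10,Chl_b,treatment,0.486,0.350
S10,Chl_a_b,treatment,2.820,0.049
S10,Car,treatment,0.673,0.148
S11,Chl,control,1.138,0.214
S11,Chl_a,control,0.844,0.169
S11,Chl_b,control,0.294,0.045
S11,Chl_a_b,control,2.859,0.181
S11,Car,control,0.460,0.059
S11,Chl,treatment,1.448,0.746
S11,Chl_a,treatment,1.043,0.491
S11,Chl_b,treatment,0.404,0.256
S11,Chl_a_b,treatment,2.751,0.374
S11,Car,treatment,0.748,0.150
S12,Chl,control,1.211,0.273
S12,Chl_a,control,0.921,0.197
S12,Chl_b,control,0.291,0.076
S12,Chl_a_b,control,3.214,0.236
S12,Car,control,0.393,0.099
S12,Chl,treatment,0.935,0.155
S12,Chl_a,treatment,0.716,0.110
S12,Chl_b,treatment,0.219,0.045
S12,Chl_a_b,treatment,3.293,0.173
S12,Car,treatment,0.435,0.221
S13,Chl,control,1.083,0.367
S13,Chl_a,control,0.805,0.270
S13,Chl_b,control,0.277,0.099
S13,Chl_a_b,control,2.937,0.250
S13,Car,control,0.608,0.181
S13,Chl,treatment,1.237,0.141
S13,Chl_a,treatment,0.920,0.087
S13,Chl_b,treatment,0.317,0.056
S13,Chl_a_b,treatment,2.934,0.267
S13,Car,treatment,0.600,0.231
S14,Chl,control,0.917,0.149
S14,Chl_a,control,0.685,0.102
S14,Chl_b,control,0.231,0.048
S14,Chl_a_b,control,2.995,0.211
S14,Car,control,0.319,0.124
S14,Chl,treatment,1.018,0.496
S14,Chl_a,treatment,0.761,0.363
S14,Chl_b,treatment,0.257,0.133
S14,Chl_a_b,treatment,3.022,0.228
S14,Car,treatment,0.510,0.165
S15,Chl,control,1.062,0.350
S15,Chl_a,control,0.707,0.199
S15,Chl_b,control,0.241,0.078
S15,Chl_a_b,control,2.941,0.057
S15,Car,control,0.468,0.087
S15,Chl,treatment,1.111,0.210
S15,Chl_a,treatment,0.837,0.157
S15,Chl_b,treatment,0.295,0.036
S15,Chl_a_b,treatment,3.065,0.104
S15,Car,treatment,0.574,0.199
S16,Chl,control,1.046,0.394
S16,Chl_a,control,0.769,0.292
S16,Chl_b,control,0.277,0.102
S16,Chl_a_b,control,2.765,0.067
S16,Car,control,0.546,0.124
S16,Chl,treatment,1.244,0.584
S16,Chl_a,treatment,0.897,0.411
S16,Chl_b,treatment,0.383,0.178
S16,Chl_a_b,treatment,2.623,0.247
S16,Car,treatment,0.634,0.111
S17,Chl,control,1.047,0.295
S17,Chl_a,control,0.772,0.211
S17,Chl_b,control,0.275,0.084
S17,Chl_a_b,control,2.823,0.170
S17,Car,control,0.564,0.209
S17,Chl,treatment,1.218,0.369
S17,Chl_a,treatment,0.911,0.261
S17,Chl_b,treatment,0.263,0.057
S17,Chl_a_b,treatment,3.015,0.254
S17,Car,treatment,0.591,0.174
S18,Chl,control,1.126,0.408
S18,Chl_a,control,0.844,0.311
S18,Chl_b,control,0.283,0.098
S18,Chl_a_b,control,2.974,0.190
S18,Car,control,0.586,0.066
S18,Chl,treatment,1.266,0.241
S18,Chl_a,treatment,0.951,0.189
S18,Chl_b,treatment,0.271,0.125
S18,Chl_a_b,treatment,3.015,0.219
S18,Car,treatment,0.687,0.075
S19,Chl,control,1.239,0.254
S19,Chl_a,control,0.907,0.199
S19,Chl_b,control,0.332,0.057
S19,Chl_a_b,control,2.715,0.186
S19,Car,control,0.517,0.047
S19,Chl,treatment,0.923,0.381
S19,Chl_a,treatment,0.680,0.281
S19,Chl_b,treatment,0.302,0.034
S19,Chl_a_b,treatment,2.818,0.178
S19,Car,treatment,0.542,0.059
S20,Chl,control,0.636,0.103
S20,Chl_a,control,0.468,0.064
S20,Chl_b,control,0.168,0.039
S20,Chl_a_b,control,2.830,0.293
S20,Car,control,0.289,0.163
S20,Chl,treatment,0.886,0.333
S20,Chl_a,treatment,0.657,0.249
S20,Chl_b,treatment,0.221,0.071
S20,Chl_a_b,treatment,2.862,0.051
S20,Car,treatment,0.565,0.069
S21,Chl,control,1.085,0.217
S21,Chl_a,control,0.803,0.166
S21,Chl_b,control,0.282,0.056
S21,Chl_a_b,control,2.850,0.352
S21,Car,control,0.414,0.052
S21,Chl,treatment,1.187,0.289
S21,Chl_a,treatment,0.871,0.218
S21,Chl_b,treatment,0.411,0.198
S21,Chl_a_b,treatment,2.774,0.329
S21,Car,treatment,0.417,0.098
S22,Chl,control,1.144,0.319
S22,Chl_a,control,0.841,0.230
S22,Chl_b,control,0.303,0.091
S22,Chl_a_b,control,2.797,0.189
S22,Car,control,0.597,0.191
S22,Chl,treatment,1.668,0.707
S22,Chl_a,treatment,1.196,0.475
S22,Chl_b,treatment,0.369,0.196
S22,Chl_a_b,treatment,2.650,0.320
S22,Car,treatment,0.677,0.115
S23,Chl,control,0.967,0.280
S23,Chl_a,control,0.722,0.210
S23,Chl_b,control,0.245,0.071
S23,Chl_a_b,control,2.947,0.191
S23,Car,control,0.439,0.113
S23,Chl,treatment,1.020,0.106
S23,Chl_a,treatment,0.751,0.860
S23,Chl_b,treatment,0.275,0.274
S23,Chl_a_b,treatment,2.789,0.164
S23,Car,treatment,0.498,0.115
S24,Chl,control,1.088,0.423
S24,Chl_a,control,0.800,0.288
S24,Chl_b,control,0.288,0.136
S24,Chl_a_b,control,2.882,0.311
S24,Car,control,0.464,0.129
S24,Chl,treatment,1.109,0.538
S24,Chl_a,treatment,0.820,0.390
S24,Chl_b,treatment,0.289,0.149
S24,Chl_a_b,treatment,2.890,0.236
S24,Car,treatment,0.506,0.215
S25,Chl,control,1.022,0.564
S25,Chl_a,control,0.755,0.419
S25,Chl_b,control,0.267,0.145
S25,Chl_a_b,control,2.817,0.175
S25,Car,control,0.471,0.217
S25,Chl,treatment,1.228,0.387
S25,Chl_a,treatment,0.907,0.266
S25,Chl_b,treatment,0.321,0.089
S25,Chl_a_b,treatment,2.816,0.082
S25,Car,treatment,0.649,0.145
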