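particle_id,worn_date,a134_bq,a134_sigma,a137_bq,a137_sigma,mask_a134_bq,mask_a134_sigma,mask_a137_bq,mask_a137_sigma,fraction_pct
Mask-001-A,2016-09-29,0.193,0.012,1.01,0.01,7.25,0.10,39.0,0.3,2.59
Mask-001-B,2016-09-29,0.0227,0.0128,0.0973,0.0050,7.25,0.10,39.0,0.3,0.250
Mask-012-A,2016-10-25,4.84,0.12,25.4,0.1,238,1,1420,3,1.79
Mask-012-B,2016-10-25,11.0,0.2,58.8,0.2,238,1,1420,3,4.14
Mask-012-C,2016-10-25,8.62,0.20,46.3,0.2,238,1,1420,3,3.26
Mask-015,2016-10-26,0.0763,0.0134,0.322,0.005,33.4,0.2,195,1,0.165
Mask-023,2016-10-26,0.0571,0.0165,0.345,0.006,10.1,0.1,57.2,0.4,0.603
Mask-037-A,2017-01-17,0.386,0.030,2.08,0.01,10.0,0.2,61.2,0.5,3.40
Mask-037-B,2017-01-17,0.185,0.020,1.12,0.01,10.0,0.2,61.2,0.5,1.82
Mask-045,2017-01-18,0.159,0.025,0.704,0.010,7.73,0.15,47.8,0.5,1.47
Mask-053,2017-01-24,0.0147,0.0091,0.126,0.004,11.7,0.2,70.1,0.6,0.180
Mask-058,2017-01-25,0.133,0.017,0.779,0.006,15.1,0.2,92.1,0.7,0.846
Mask-067,2017-04-20,0.0397,0.0189,0.276,0.009,4.63,0.12,30.7,0.4,0.900
Mask-083,2017-05-16,0.0762,0.0136,0.464,0.006,3.20,0.10,21.3,0.3,2.18
Mask-087-A,2017-05-17,0.0260,0.0095,0.146,0.004,9.25,0.16,65.9,0.6,0.222
Mask-087-B,2017-05-17,0.0751,0.0205,0.547,0.010,9.25,0.16,65.9,0.6,0.831
Mask-087-C,2017-05-17,LDL,,0.0468,0.0020,9.25,0.16,65.9,0.6,0.071
Mask-087-D,2017-05-17,0.0299,0.0121,0.193,0.004,9.25,0.16,65.9,0.6,0.294
Mask-087-E,2017-05-17,0.0251,0.0095,0.119,0.004,9.25,0.16,65.9,0.6,0.181
Mask-087-F,2017-05-17,0.0326,0.0102,0.204,0.004,9.25,0.16,65.9,0.6,0.309
Mask-087-G,2017-05-17,LDL,,0.0805,0.0023,9.25,0.16,65.9,0.6,0.122
Mask-090,2017-05-17,0.107,0.017,0.652,0.007,14.1,1.9,96.4,0.7,0.676
Mask-101,2017-05-25,0.0439,0.0133,0.352,0.005,1.55,0.08,10.5,0.2,3.35
Mask-114,2017-06-15,0.0248,0.0076,0.130,0.003,1.65,0.09,12.2,0.2,1.06
Mask-126,2017-07-11,0.116,0.019,0.681,0.009,18.8,0.2,131,1,0.520
Mask-127-A,2017-07-11,0.0964,0.0183,0.571,0.009,12.2,0.2,84.4,0.6,0.677
Mask-127-B,2017-07-11,0.0556,0.0109,0.353,0.005,12.2,0.2,84.4,0.6,0.418
Mask-127-C,2017-07-11,0.0529,0.0135,0.357,0.005,12.2,0.2,84.4,0.6,0.423
Mask-127-D,2017-07-11,0.0334,0.0119,0.261,0.005,12.2,0.2,84.4,0.6,0.309
Mask-127-E,2017-07-11,0.305,0.028,1.89,0.01,12.2,0.2,84.4,0.6,2.24
Mask-142,2017-08-29,0.0556,0.0155,0.465,0.007,3.08,0.11,24.2,0.3,1.92
Mask-197,2017-11-08,0.0575,0.0104,0.298,0.005,2.11,0.09,16.6,0.3,1.79
Mask-242-A,2018-05-30,0.177,0.021,1.71,0.01,1.37,0.05,12.9,0.2,13.2
Mask-242-B,2018-05-30,0.0699,0.0151,0.633,0.010,1.37,0.05,12.9,0.2,4.90
Mask-243-A,2018-05-30,0.0970,0.0121,0.850,0.008,4.15,0.07,39.3,0.3,2.16
Mask-243-B,2018-05-30,0.0343,0.0074,0.352,0.005,4.15,0.07,39.3,0.3,0.897
Mask-243-C,2018-05-30,0.0552,0.0133,0.441,0.009,4.15,0.07,39.3,0.3,1.12
Mask-246,2018-07-09,0.0184,0.0067,0.193,0.004,0.871,0.072,8.34,0.21,2.31
Mask-253,2018-09-26,0.0421,0.0082,0.384,0.006,1.03,0.07,8.87,0.21,4.32
Mask-256,2018-09-26,0.0645,0.0132,0.661,0.010,0.880,0.036,8.69,0.13,7.60
Mask-275,2018-11-30,0.0245,0.0070,0.246,0.005,1.30,0.11,14.1,0.3,1.75
Mask-276,2018-11-30,0.0164,0.0057,0.132,0.004,2.18,0.05,24.3,0.2,0.543
Mask-282,2019-01-23,0.0377,0.0082,0.421,0.005,5.72,0.18,60.2,0.5,0.700
Mask-283,2019-01-24,0.0570,0.0098,0.649,0.006,3.41,0.19,34.4,0.4,1.89
Mask-284-A,2019-01-24,0.0591,0.0111,0.636,0.009,17.9,0.3,196,1,0.324
Mask-284-B,2019-01-24,0.0101,0.0059,0.168,0.004,17.9,0.3,196,1,0.0859
Mask-284-C,2019-01-24,0.0253,0.0052,0.246,0.004,17.9,0.3,196,1,0.126
Mask-284-D,2019-01-24,LDL,,0.0142,0.0015,17.9,0.3,196,1,0.00723
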