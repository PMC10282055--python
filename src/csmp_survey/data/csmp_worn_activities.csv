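particle_id,residence_id,measurement_date,live_time_s,a134_bq,a134_sigma,a137_bq,a137_sigma,previously_reported
Mask-001-A,ID_09,2016-12-06,200000,0.193,0.012,1.01,0.01,true
Mask-012-A,ID_14,2016-12-02,50000,4.84,0.116,25.4,0.1,true
Mask-012-B,ID_14,2016-12-03,30000,11.0,0.2,58.8,0.2,true
Mask-012-C,ID_14,2016-12-03,30000,8.62,0.20,46.3,0.2,true
Mask-001-B,ID_09,2019-07-14,200000,0.0227,0.0129,0.0973,0.0050,false
Mask-015,ID_14,2019-08-23,500000,0.0763,0.0134,0.322,0.005,false
Mask-023,ID_03,2020-01-22,500000,0.0572,0.0165,0.345,0.006,false
Mask-037-A,ID_18,2019-10-01,500000,0.387,0.031,2.08,0.012,false
Mask-037-B,ID_18,2019-06-25,500000,0.185,0.020,1.12,0.009,false
Mask-045,ID_19,2019-09-17,280000,0.159,0.025,0.704,0.010,false
Mask-055,ID_20,2019-10-07,600000,0.0147,0.0091,0.126,0.004,false
Mask-058,ID_21,2020-02-27,600000,0.133,0.017,0.779,0.006,false
Mask-067,ID_22,2019-07-04,200000,0.0397,0.0190,0.276,0.009,false
Mask-083,ID_24,2019-12-20,600000,0.0763,0.0136,0.464,0.006,false
Mask-087-A,ID_24,2020-03-10,600000,0.0260,0.0095,0.146,0.004,false
Mask-087-B,ID_24,2019-07-23,200000,0.0752,0.0205,0.547,0.010,false
Mask-087-C,ID_24,2020-06-17,600000,LDL,,0.0468,0.0020,false
Mask-087-D,ID_24,2020-05-09,515000,0.0299,0.0121,0.193,0.004,false
Mask-087-E,ID_24,2020-05-15,600000,0.0252,0.0095,0.119,0.004,false
Mask-087-F,ID_24,2020-01-07,600000,0.0326,0.0102,0.204,0.004,false
Mask-087-G,ID_24,2020-06-23,600000,LDL,,0.0805,0.0023,false
Mask-090,ID_24,2020-04-15,600000,0.107,0.017,0.652,0.007,false
Mask-101,ID_26,2020-04-08,600000,0.0439,0.0133,0.352,0.005,false
Mask-114,ID_28,2020-06-10,600000,0.0241,0.0074,0.132,0.003,false
Mask-126-A,ID_01,2019-06-17,200000,0.0965,0.0183,0.571,0.009,false
Mask-126-B,ID_01,2019-06-19,500000,0.0556,0.0109,0.353,0.005,false
Mask-126-C,ID_01,2020-06-05,400000,0.0513,0.0131,0.363,0.005,false
Mask-126-D,ID_01,2020-05-29,595000,0.0334,0.0119,0.261,0.005,false
Mask-126-E,ID_01,2020-05-22,600000,0.306,0.028,1.89,0.01,false
Mask-127,ID_01,2019-08-19,300000,0.116,0.019,0.681,0.009,false
Mask-142,ID_30,2019-10-21,350000,0.0556,0.0155,0.465,0.007,false
Mask-197,ID_39,2020-01-15,600000,0.0576,0.0104,0.298,0.005,false
Mask-242-A,ID_48,2019-04-27,200000,0.177,0.021,1.71,0.01,false
Mask-242-B,ID_48,2019-05-09,200000,0.0699,0.0151,0.633,0.010,false
Mask-243-A,ID_48,2019-05-16,400000,0.0971,0.0121,0.850,0.008,false
Mask-243-B,ID_48,2019-05-22,500000,0.0343,0.0074,0.352,0.005,false
Mask-243-C,ID_48,2019-05-17,200000,0.0552,0.0133,0.441,0.009,false
Mask-246,ID_49,2019-09-09,500000,0.0184,0.0067,0.193,0.004,false
Mask-253,ID_50,2019-10-15,520000,0.0421,0.0082,0.384,0.006,false
Mask-256,ID_50,2019-05-24,200000,0.0645,0.0132,0.661,0.010,false
Mask-275,ID_56,2019-10-30,500000,0.0245,0.0070,0.246,0.005,false
Mask-276,ID_56,2020-04-22,600000,0.0164,0.0057,0.132,0.004,false
Mask-282,ID_60,2020-03-17,590000,0.0377,0.0082,0.421,0.005,false
Mask-283,ID_61,2020-03-24,600000,0.0570,0.0098,0.649,0.006,false
Mask-284-A,ID_61,2019-08-05,200000,0.0592,0.0111,0.636,0.009,false
Mask-284-B,ID_61,2020-04-30,600000,0.0101,0.0059,0.168,0.004,false
Mask-284-C,ID_61,2019-08-09,600000,0.0253,0.0052,0.246,0.004,false
Mask-284-D,ID_61,2020-07-07,600000,LDL,,0.0142,0.0015,false
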