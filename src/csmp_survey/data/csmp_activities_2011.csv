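particle_id,a134_2011_bq,a134_2011_sigma,a137_2011_bq,a137_2011_sigma,volume_cm3,diameter_um
Mask-001-A,1.25,0.08,1.15,0.01,2.51e-12,3.61
Mask-001-B,0.147,0.083,0.111,0.006,4.72e-13,2.07
Mask-015,0.506,0.089,0.367,0.006,1.11e-12,2.76
Mask-023,0.379,0.109,0.393,0.006,1.17e-12,2.80
Mask-037-A,2.76,0.22,2.38,0.01,4.22e-12,4.30
Mask-037-B,1.32,0.15,1.28,0.01,2.71e-12,3.71
Mask-045,1.14,0.18,0.806,0.012,1.95e-12,3.32
Mask-053,0.106,0.066,0.144,0.004,5.70e-13,2.21
Mask-058,0.956,0.125,0.893,0.007,2.09e-12,3.40
Mask-067,0.309,0.148,0.318,0.010,1.00e-12,2.66
Mask-083,0.608,0.108,0.535,0.007,1.45e-12,3.01
Mask-087-A,0.208,0.076,0.169,0.004,6.37e-13,2.29
Mask-087-B,0.600,0.164,0.631,0.011,1.64e-12,3.14
Mask-087-C,LDL,,0.0540,0.0023,2.82e-13,1.75
Mask-087-D,0.239,0.096,0.223,0.005,7.78e-13,2.45
Mask-087-E,0.201,0.076,0.138,0.004,5.51e-13,2.18
Mask-087-F,0.260,0.081,0.235,0.005,8.08e-13,2.48
Mask-087-G,LDL,,0.0928,0.0026,4.16e-13,1.99
Mask-090,0.853,0.139,0.752,0.008,1.85e-12,3.27
Mask-101,0.353,0.107,0.406,0.006,1.19e-12,2.82
Mask-114,0.198,0.061,0.153,0.003,5.94e-13,2.24
Mask-126,0.976,0.156,0.788,0.011,1.92e-12,3.31
Mask-127-A,0.810,0.154,0.661,0.011,1.69e-12,3.17
Mask-127-B,0.467,0.092,0.408,0.006,1.20e-12,2.83
Mask-127-C,0.431,0.110,0.420,0.006,1.22e-12,2.85
Mask-127-D,0.280,0.100,0.302,0.005,9.65e-13,2.63
Mask-127-E,2.57,0.24,2.19,0.01,3.98e-12,4.22
Mask-142,0.489,0.136,0.540,0.009,1.46e-12,3.02
Mask-197,0.540,0.097,0.347,0.006,1.07e-12,2.72
Mask-242-A,2.00,0.24,2.02,0.02,3.75e-12,4.13
Mask-242-B,0.790,0.171,0.748,0.012,1.85e-12,3.26
Mask-243-A,1.10,0.14,1.00,0.01,2.28e-12,3.50
Mask-243-B,0.388,0.084,0.416,0.006,1.21e-12,2.84
Mask-243-C,0.624,0.150,0.521,0.011,1.43e-12,2.99
Mask-246,0.216,0.079,0.228,0.005,7.91e-13,2.46
Mask-253,0.531,0.103,0.457,0.007,1.30e-12,2.90
Mask-256,0.813,0.166,0.787,0.012,1.91e-12,3.30
Mask-275,0.328,0.093,0.294,0.006,9.48e-13,2.61
Mask-276,0.220,0.077,0.158,0.004,6.08e-13,2.25
Mask-282,0.531,0.116,0.505,0.007,1.40e-12,2.97
Mask-283,0.803,0.139,0.779,0.008,1.90e-12,3.30
Mask-284-A,0.833,0.156,0.763,0.010,1.87e-12,3.28
Mask-284-B,0.142,0.083,0.202,0.005,7.24e-13,2.39
Mask-284-C,0.356,0.073,0.296,0.005,9.51e-12,2.62
Mask-284-D,LDL,,0.0170,0.0018,1.24e-13,1.33
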