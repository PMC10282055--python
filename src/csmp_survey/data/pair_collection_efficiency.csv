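outer_mask_id,residence_id,mask_role,person,a137_outer_bq,efficiency_pct
Mask-032,ID_18,outer,1,0.785,56.6
Mask-034,ID_18,outer,3,6.07,78.7
Mask-038,ID_18,outer,3,14.4,15.4
Mask-040,ID_19,outer,1,2.72,4.96
Mask-042,ID_19,outer,3,6.47,67.9
Mask-050,ID_20,outer,2,87.7,30.9
Mask-052,ID_20,outer,3,8.35,55.7
Mask-054,ID_20,outer,1,102,31.1
Mask-056,ID_20,outer,3,7.91,8.73
Mask-058,ID_21,outer,1,92.1,34.3
Mask-060,ID_21,outer,2,130,34.3
Mask-062,ID_21,outer,3,20.5,55.5
Mask-064,ID_22,outer,1,50.7,42.1
Mask-068,ID_23,outer,1,38.4,56.5
Mask-073,ID_23,outer,3,13.4,56.5
Mask-074,ID_24,outer,3,4.26,36.7
Mask-076,ID_24,outer,4,9.05,24.1
Mask-078,ID_24,outer,1,39.7,21.0
Mask-080,ID_24,outer,3,23.9,18.7
Mask-082,ID_24,outer,4,32.7,35.0
Mask-084,ID_24,outer,1,57.9,37.4
Mask-090,ID_24,outer,4,96.4,1.37
Mask-092,ID_24,outer,4,75.8,2.53
Mask-094,ID_25,outer,1,161,44.4
Mask-096,ID_25,outer,3,2.75,66.4
Mask-098,ID_25,outer,4,2.42,25.3
Mask-100,ID_26,outer,1,13.8,24.0
Mask-102,ID_26,outer,2,23.9,24.5
Mask-104,ID_26,outer,3,14.5,5.04
Mask-106,ID_26,outer,5,9.95,9.23
Mask-110,ID_27,outer,3,3.56,40.3
Mask-112,ID_27,outer,5,7.87,22.0
Mask-122,ID_01;ID_02,outer,5,108,5.25
Mask-131,ID_29,outer,5,21.6,38.9
Mask-133,ID_29,outer,1,21.5,25.8
Mask-139,ID_30,outer,4,5.48,81.7
Mask-143,ID_30,outer,2,21.3,12.2
Mask-149,ID_31,outer,1,6.32,27.5
Mask-155,ID_32,outer,3,1.02,23.8
Mask-157,ID_32,outer,4,0.534,33.6
Mask-163,ID_32,outer,4,0.667,33.9
Mask-166,ID_33,outer,1,15.0,5.31
Mask-168,ID_34,outer,1,3.96,45.1
Mask-171,ID_35,outer,1,55.4,75.6
Mask-181,ID_33;ID_34;ID_35,outer,5,2.43,51.5
Mask-183,ID_33;ID_34;ID_35,outer,3,1.67,33.2
Mask-187,ID_36,outer,5,3.11,46.6
Mask-190,ID_37,outer,5,1.12,48.0
Mask-201,ID_40A,outer,2,8.53,16.3
Mask-254,ID_50,outer,1,5.75,19.1
Mask-263,ID_51,outer,1,10.9,79.4
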