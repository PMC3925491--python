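area,zone,kp_start,kp_end,flow_direction,Qf_m3_day,bank_length_m
A1,Z1,116,114.5,losing,-668,1547
A1,Z2,114.5,112,losing,-52,531
A1,Z2,114.5,112,gaining,393,3545
A2,Z3,113,111,losing,-1890,2040
A2,Z4,111,109,gaining,6097,2809
A3,Z5,111,110,losing,-354,587
A3,Z5,110.5,110,gaining,5,76
A3,Z6,110,106,losing,-77,431
A3,Z6,110,106,gaining,1723,3709
A3,Z7,106,102.5,losing,-462,3057
A3,Z7,106,102.5,gaining,8,349
A3,Z8,102.5,99,losing,-35,21
A3,Z8,102.5,99,gaining,54340,4190
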