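batch,group,mean_g,sem_g,n,marker_vs_control,marker_vs_model,inhibition_pct,inhibition_sem_pct
S1,control,0.4483,0.04920,6,,,,
S1,model,1.426,0.1244,6,##,,,
S1,dose_15,1.341,0.0984,6,,,,
S1,dose_25,0.6487,0.0472,6,,**,78.02,5.549
S1,dose_35,0.4776,0.0430,6,,**,97.05,4.003
S2,control,0.5204,0.01452,6,,,,
S2,model,1.168,0.1892,6,#,,,
S2,dose_15,1.194,0.1848,6,,,,
S2,dose_25,0.6943,0.1398,6,,,82.90,12.32
S2,dose_35,0.4543,0.06812,6,,**,120.3,9.962
S3,control,0.4285,0.03723,6,,,,
S3,model,1.216,0.1397,6,##,,,
S3,dose_15,0.9784,0.1218,6,,,,
S3,dose_25,0.5199,0.05595,6,,**,88.08,3.246
S3,dose_35,0.3260,0.02184,6,,**,114.2,2.65
S4,control,0.5635,0.06599,6,,,,
S4,model,1.914,0.3118,6,##,,,
S4,dose_15,1.703,0.2831,6,,,,
S4,dose_25,0.8390,0.07993,6,,**,86.11,9.202
S4,dose_35,0.5414,0.05365,6,,**,111,8.952
S5,control,0.4279,0.06277,6,,,,
S5,model,1.358,0.1667,6,##,,,
S5,dose_15,1.160,0.1562,6,,,,
S5,dose_25,0.5640,0.08049,6,,**,84.74,5.133
S5,dose_35,0.4190,0.06737,6,,**,101.6,2.695
S6,control,0.5296,0.04119,6,,,,
S6,model,1.159,0.09607,6,##,,,
S6,dose_15,0.9905,0.09806,6,,,,
S6,dose_25,0.6552,0.05702,6,,**,82.45,5.394
S6,dose_35,0.5028,0.03212,6,,**,103.9,3.426
S7,control,0.4323,0.06757,6,,,,
S7,model,1.124,0.1909,6,##,,,
S7,dose_15,0.7886,0.05031,6,,,,
S7,dose_25,0.3899,0.03225,6,,**,99.13,9.353
S7,dose_35,0.2655,0.0438,6,,**,120.2,7.817
S8,control,0.5116,0.04533,6,,,,
S8,model,0.9918,0.05947,6,##,,,
S8,dose_15,1.001,0.03622,6,,,,
S8,dose_25,0.7059,0.02238,6,,**,58.10,8.560
S8,dose_35,0.5774,0.01672,6,,**,85.36,7.416
S9,control,0.4842,0.05229,6,,,,
S9,model,1.063,0.1186,6,#,,,
S9,dose_15,0.984,0.2091,6,,,,
S9,dose_25,0.6202,0.09016,6,,,75.91,7.580
S9,dose_35,0.3968,0.0398,6,,**,113.4,6.972
S10,control,0.4960,0.05865,6,,,,
S10,model,1.409,0.1962,6,##,,,
S10,dose_15,0.9719,0.08651,6,,*,,
S10,dose_25,0.4914,0.04814,6,,**,104.2,5.288
S10,dose_35,0.368,0.05182,6,,**,120.4,10.35
S11,control,0.3607,0.04392,6,,,,
S11,model,0.9241,0.1457,6,##,,,
S11,dose_15,0.5863,0.07636,6,,,,
S11,dose_25,0.3203,0.04721,6,,***,110.2,4.840
S11,dose_35,0.2587,0.05415,6,,**,117.5,10.68
S12,control,0.3917,0.03975,6,,,,
S12,model,1.433,0.2150,6,##,,,
S12,dose_15,1.249,0.2104,6,,,,
S12,dose_25,0.6738,0.1062,6,,**,75.15,5.218
S12,dose_35,0.4462,0.07728,6,,**,98.39,5.121
S13,control,0.5547,0.09259,6,,,,
S13,model,1.113,0.1566,6,#,,,
S13,dose_15,0.9223,0.1112,6,,,,
S13,dose_25,0.5019,0.0944,6,,**,107.4,7.044
S13,dose_35,0.4470,0.09103,6,,**,118,6.441
S14,control,0.4113,0.03592,6,,,,
S14,model,0.8625,0.08512,6,##,,,
S14,dose_15,0.6173,0.05789,6,,*,,
S14,dose_25,0.3951,0.03806,6,,**,108.9,7.633
S14,dose_35,0.3036,0.02892,6,,**,127.4,5.618
S15,control,0.4967,0.02877,6,,,,
S15,model,1.243,0.2305,6,#,,,
S15,dose_15,1.117,0.2264,6,,,,
S15,dose_25,0.7182,0.1251,6,,,67.52,9.100
S15,dose_35,0.5096,0.06343,6,,*,94.27,5.152
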