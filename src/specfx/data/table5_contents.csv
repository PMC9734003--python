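peak,compound,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10,S11,S12,S13,S14,S15
X1,oxypaeoniflorin,0.080,0.104,0.083,0.070,0.090,0.092,0.077,0.088,0.094,0.086,0.102,0.113,0.221,0.229,0.113
X2,catechin,0.753,0.490,0.546,0.501,0.410,0.591,0.563,0.335,0.381,0.552,0.625,0.457,0.950,0.652,0.544
X3,albiflorin,1.634,2.690,2.067,2.265,2.238,2.044,1.789,2.079,1.705,1.807,2.200,2.225,3.000,3.259,3.490
X4,paeoniflorin,3.586,3.666,3.966,3.035,4.161,4.028,3.659,3.456,3.266,3.866,4.042,4.175,2.737,2.500,3.365
X5,liquiritin,2.431,3.023,2.172,2.084,2.814,2.623,2.105,1.664,2.417,2.508,2.348,2.411,2.912,2.764,2.976
X6,galloylpaeoniflorin,0.082,0.096,0.108,0.087,0.103,0.100,0.102,0.101,0.073,0.083,0.085,0.095,0.064,0.055,0.157
X7,pentagalloylglucose,0.103,0.111,0.116,0.116,0.140,0.116,0.120,0.105,0.104,0.168,0.144,0.174,0.178,0.181,0.374
X8,ononin,0.360,0.575,0.497,0.366,0.555,0.518,0.422,0.437,0.474,0.454,0.482,0.591,0.503,0.436,0.568
X9,isoliquiritin,0.128,0.121,0.104,0.100,0.153,0.140,0.098,0.072,0.117,0.135,0.117,0.101,0.136,0.152,0.151
X10,licochalcone B,0.002,0.003,0.007,0.004,0.002,0.004,0.003,0.002,0.002,0.001,0.007,0.007,0.006,0.004,0.001
X11,liquiritigenin,0.588,0.401,0.323,0.497,0.488,0.362,0.365,0.382,0.597,0.843,0.936,0.294,0.871,0.711,0.392
X12,benzoylpaeoniflorin,0.007,0.005,0.005,0.008,0.004,0.008,0.007,0.011,0.010,0.011,0.012,0.013,0.016,0.016,0.020
X16,glycyrrhizic acid,1.615,1.367,1.410,1.358,1.663,1.663,1.554,1.108,1.803,2.060,1.904,1.583,2.209,2.131,1.477
X18,licochalcone A,0.521,0.151,0.223,0.232,0.115,0.158,0.274,0.196,0.167,0.410,0.263,0.218,0.390,0.370,0.292
X19,glabridin,0.026,0.014,0.028,0.039,0.014,0.016,0.037,0.029,0.028,0.049,0.040,0.033,0.051,0.042,0.026
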