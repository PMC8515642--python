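,A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
A,0,0.4642,0.2145,0.3888,0.1787,0.3142,0.4315,0.1919,0.2337,0.4683,0.3803,0.4476,0.3332,0.4773,0.1322,0.2072,0.1890,0.6407,0.4573,0.3020
R,0.4642,0,0.3261,0.2664,0.4909,0.3071,0.2002,0.5086,0.3570,0.6162,0.5314,0.0234,0.4818,0.6058,0.3467,0.4131,0.3841,0.7284,0.5657,0.5257
N,0.2145,0.3261,0,0.2615,0.3231,0.1040,0.2679,0.2303,0.2314,0.5577,0.4425,0.3132,0.3934,0.5301,0.1349,0.1277,0.0601,0.6797,0.4918,0.4059
D,0.3888,0.2664,0.2615,0,0.5057,0.2817,0.0970,0.3323,0.4280,0.7328,0.6386,0.2468,0.5822,0.7316,0.3297,0.2563,0.3117,0.8805,0.6951,0.5955
C,0.1787,0.4909,0.3231,0.5057,0,0.4015,0.5283,0.3706,0.1758,0.2919,0.2214,0.4791,0.1792,0.3190,0.1934,0.3685,0.3067,0.4833,0.3099,0.1288
Q,0.3142,0.3071,0.1040,0.2817,0.4015,0,0.2544,0.3171,0.2739,0.6017,0.4795,0.3001,0.4352,0.5560,0.2195,0.2045,0.1368,0.6920,0.5116,0.4634
E,0.4315,0.2002,0.2679,0.0970,0.5283,0.2544,0,0.3965,0.4201,0.7287,0.6299,0.1858,0.5759,0.7160,0.3459,0.3010,0.3248,0.8554,0.6754,0.6018
G,0.1919,0.5086,0.2303,0.3323,0.3706,0.3171,0.3965,0,0.3873,0.6586,0.5631,0.4896,0.5156,0.6575,0.2579,0.1165,0.2066,0.8178,0.6320,0.4917
H,0.2337,0.3570,0.2314,0.4280,0.1758,0.2739,0.4201,0.3873,0,0.3305,0.2165,0.3504,0.1653,0.3074,0.1345,0.3311,0.2351,0.4617,0.2722,0.1967
I,0.4683,0.6162,0.5577,0.7328,0.2919,0.6017,0.7287,0.6586,0.3305,0,0.1311,0.6137,0.1667,0.1300,0.4382,0.6381,0.5506,0.2431,0.1663,0.1677
L,0.3803,0.5314,0.4425,0.6386,0.2214,0.4795,0.6299,0.5631,0.2165,0.1311,0,0.5290,0.0584,0.1024,0.3342,0.5308,0.4335,0.2667,0.0944,0.1021
K,0.4476,0.0234,0.3132,0.2468,0.4791,0.3001,0.1858,0.4896,0.3504,0.6137,0.5290,0,0.4780,0.6062,0.3329,0.3961,0.3715,0.7326,0.5668,0.5189
M,0.3332,0.4818,0.3934,0.5822,0.1792,0.4352,0.5759,0.5156,0.1653,0.1667,0.0584,0.4780,0,0.1591,0.2810,0.4813,0.3878,0.3216,0.1422,0.0798
F,0.4773,0.6058,0.5301,0.7316,0.3190,0.5560,0.7160,0.6575,0.3074,0.1300,0.1024,0.6062,0.1591,0,0.4306,0.6230,0.5195,0.1651,0.0521,0.1953
P,0.1322,0.3467,0.1349,0.3297,0.1934,0.2195,0.3459,0.2579,0.1345,0.4382,0.3342,0.3329,0.2810,0.4306,0,0.2056,0.1386,0.5898,0.3998,0.2825
S,0.2072,0.4131,0.1277,0.2563,0.3685,0.2045,0.3010,0.1165,0.3311,0.6381,0.5308,0.3961,0.4813,0.6230,0.2056,0,0.1206,0.7788,0.5901,0.4756
T,0.1890,0.3841,0.0601,0.3117,0.3067,0.1368,0.3248,0.2066,0.2351,0.5506,0.4335,0.3715,0.3878,0.5195,0.1386,0.1206,0,0.6699,0.4832,0.3933
W,0.6407,0.7284,0.6797,0.8805,0.4833,0.6920,0.8554,0.8178,0.4617,0.2431,0.2667,0.7326,0.3216,0.1651,0.5898,0.7788,0.6699,0,0.1901,0.3580
Y,0.4573,0.5657,0.4918,0.6951,0.3099,0.5116,0.6754,0.6320,0.2722,0.1663,0.0944,0.5668,0.1422,0.0521,0.3998,0.5901,0.4832,0.1901,0,0.1951
V,0.3020,0.5257,0.4059,0.5955,0.1288,0.4634,0.6018,0.4917,0.1967,0.1677,0.1021,0.5189,0.0798,0.1953,0.2825,0.4756,0.3933,0.3580,0.1951,0
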