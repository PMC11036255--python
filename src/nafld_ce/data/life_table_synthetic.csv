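age,sex,q,cv_frac,liver_frac
0,female,0.000516,0.22,0.035
1,female,0.00051759,0.2222,0.0347
2,female,0.00051935,0.2244,0.0344
3,female,0.00052128,0.2266,0.0341
4,female,0.0005234,0.2288,0.0338
5,female,0.00052573,0.231,0.0335
6,female,0.00052829,0.2332,0.0332
7,female,0.00053111,0.2354,0.0329
8,female,0.00053421,0.2376,0.0326
9,female,0.00053762,0.2398,0.0323
10,female,0.00054137,0.242,0.032
11,female,0.00054549,0.2442,0.0317
12,female,0.00055003,0.2464,0.0314
13,female,0.00055501,0.2486,0.0311
14,female,0.0005605,0.2508,0.0308
15,female,0.00056653,0.253,0.0305
16,female,0.00057316,0.2552,0.0302
17,female,0.00058045,0.2574,0.0299
18,female,0.00058846,0.2596,0.0296
19,female,0.00059728,0.2618,0.0293
20,female,0.00060697,0.264,0.029
21,female,0.00061764,0.2662,0.0287
22,female,0.00062936,0.2684,0.0284
23,female,0.00064225,0.2706,0.0281
24,female,0.00065643,0.2728,0.0278
25,female,0.00067202,0.275,0.0275
26,female,0.00068916,0.2772,0.0272
27,female,0.00070801,0.2794,0.0269
28,female,0.00072874,0.2816,0.0266
29,female,0.00075154,0.2838,0.0263
30,female,0.0007766,0.286,0.026
31,female,0.00080417,0.2882,0.0257
32,female,0.00083448,0.2904,0.0254
33,female,0.00086782,0.2926,0.0251
34,female,0.00090447,0.2948,0.0248
35,female,0.00094478,0.297,0.0245
36,female,0.00098911,0.2992,0.0242
37,female,0.00103785,0.3014,0.0239
38,female,0.00109146,0.3036,0.0236
39,female,0.0011504,0.3058,0.0233
40,female,0.00121522,0.308,0.023
41,female,0.0012865,0.3102,0.0227
42,female,0.00136488,0.3124,0.0224
43,female,0.00145107,0.3146,0.0221
44,female,0.00154585,0.3168,0.0218
45,female,0.00165008,0.319,0.0215
46,female,0.0017647,0.3212,0.0212
47,female,0.00189074,0.3234,0.0209
48,female,0.00202934,0.3256,0.0206
49,female,0.00218175,0.3278,0.0203
50,female,0.00234935,0.33,0.02
51,female,0.00253365,0.3322,0.0197
52,female,0.00273632,0.3344,0.0194
53,female,0.00295919,0.3366,0.0191
54,female,0.00320427,0.3388,0.0188
55,female,0.00347378,0.341,0.0185
56,female,0.00377014,0.3432,0.0182
57,female,0.00409604,0.3454,0.0179
58,female,0.00445442,0.3476,0.0176
59,female,0.00484851,0.3498,0.0173
60,female,0.00528188,0.352,0.017
61,female,0.00575843,0.3542,0.0167
62,female,0.00628248,0.3564,0.0164
63,female,0.00685876,0.3586,0.0161
64,female,0.00749247,0.3608,0.0158
65,female,0.00818933,0.363,0.0155
66,female,0.00895564,0.3652,0.0152
67,female,0.00979832,0.3674,0.0149
68,female,0.01072498,0.3696,0.0146
69,female,0.01174399,0.3718,0.0143
70,female,0.01286455,0.374,0.014
71,female,0.01409679,0.3762,0.0137
72,female,0.01545183,0.3784,0.0134
73,female,0.01694191,0.3806,0.0131
74,female,0.01858049,0.3828,0.0128
75,female,0.02038237,0.385,0.0125
76,female,0.02236382,0.3872,0.0122
77,female,0.02454275,0.3894,0.0119
78,female,0.02693882,0.3916,0.0116
79,female,0.02957368,0.3938,0.0113
80,female,0.03247113,0.396,0.011
81,female,0.03565734,0.3982,0.0107
82,female,0.03916108,0.4004,0.0104
83,female,0.043014,0.4026,0.0101
84,female,0.0472509,0.4048,0.0098
85,female,0.05191004,0.407,0.0095
86,female,0.0570335,0.4092,0.0092
87,female,0.06266757,0.4114,0.0089
88,female,0.06886312,0.4136,0.0086
89,female,0.07567611,0.4158,0.0083
90,female,0.08316807,0.418,0.008
91,female,0.09140668,0.4202,0.0077
92,female,0.10046633,0.4224,0.0074
93,female,0.11042886,0.4246,0.0071
94,female,0.12138425,0.4268,0.0068
95,female,0.13343143,0.429,0.0065
96,female,0.14667923,0.4312,0.0062
97,female,0.16124728,0.4334,0.0059
98,female,0.17726717,0.4356,0.0056
99,female,0.19488358,0.4378,0.0053
100,female,0.21425563,0.44,0.005
101,female,0.23555827,0.4422,0.005
102,female,0.25898391,0.4444,0.005
103,female,0.28474412,0.4466,0.005
104,female,0.31307156,0.4488,0.005
105,female,0.34422209,0.45,0.005
106,female,0.37847704,0.45,0.005
107,female,0.4161458,0.45,0.005
108,female,0.45756858,0.45,0.005
109,female,0.50311951,0.45,0.005
110,female,0.55321,0.45,0.005
0,male,0.000526,0.22,0.035
1,male,0.00052853,0.2222,0.0347
2,male,0.00053131,0.2244,0.0344
3,male,0.00053437,0.2266,0.0341
4,male,0.00053772,0.2288,0.0338
5,male,0.00054139,0.231,0.0335
6,male,0.00054543,0.2332,0.0332
7,male,0.00054985,0.2354,0.0329
8,male,0.00055471,0.2376,0.0326
9,male,0.00056005,0.2398,0.0323
10,male,0.0005659,0.242,0.032
11,male,0.00057232,0.2442,0.0317
12,male,0.00057937,0.2464,0.0314
13,male,0.0005871,0.2486,0.0311
14,male,0.00059559,0.2508,0.0308
15,male,0.00060491,0.253,0.0305
16,male,0.00061513,0.2552,0.0302
17,male,0.00062636,0.2574,0.0299
18,male,0.00063867,0.2596,0.0296
19,male,0.00065218,0.2618,0.0293
20,male,0.00066702,0.264,0.029
21,male,0.00068329,0.2662,0.0287
22,male,0.00070116,0.2684,0.0284
23,male,0.00072076,0.2706,0.0281
24,male,0.00074228,0.2728,0.0278
25,male,0.00076589,0.275,0.0275
26,male,0.00079181,0.2772,0.0272
27,male,0.00082025,0.2794,0.0269
28,male,0.00085146,0.2816,0.0266
29,male,0.00088571,0.2838,0.0263
30,male,0.00092331,0.286,0.026
31,male,0.00096456,0.2882,0.0257
32,male,0.00100984,0.2904,0.0254
33,male,0.00105953,0.2926,0.0251
34,male,0.00111406,0.2948,0.0248
35,male,0.00117391,0.297,0.0245
36,male,0.00123959,0.2992,0.0242
37,male,0.00131167,0.3014,0.0239
38,male,0.00139078,0.3036,0.0236
39,male,0.0014776,0.3058,0.0233
40,male,0.00157287,0.308,0.023
41,male,0.00167744,0.3102,0.0227
42,male,0.00179219,0.3124,0.0224
43,male,0.00191813,0.3146,0.0221
44,male,0.00205635,0.3168,0.0218
45,male,0.00220803,0.319,0.0215
46,male,0.0023745,0.3212,0.0212
47,male,0.00255719,0.3234,0.0209
48,male,0.00275769,0.3256,0.0206
49,male,0.00297773,0.3278,0.0203
50,male,0.00321921,0.33,0.02
51,male,0.00348423,0.3322,0.0197
52,male,0.00377508,0.3344,0.0194
53,male,0.00409427,0.3366,0.0191
54,male,0.00444458,0.3388,0.0188
55,male,0.00482902,0.341,0.0185
56,male,0.00525093,0.3432,0.0182
57,male,0.00571397,0.3454,0.0179
58,male,0.00622213,0.3476,0.0176
59,male,0.00677982,0.3498,0.0173
60,male,0.00739186,0.352,0.017
61,male,0.00806355,0.3542,0.0167
62,male,0.00880071,0.3564,0.0164
63,male,0.00960971,0.3586,0.0161
64,male,0.01049756,0.3608,0.0158
65,male,0.01147194,0.363,0.0155
66,male,0.01254129,0.3652,0.0152
67,male,0.01371485,0.3674,0.0149
68,male,0.01500279,0.3696,0.0146
69,male,0.01641626,0.3718,0.0143
70,male,0.01796749,0.374,0.014
71,male,0.0196699,0.3762,0.0137
72,male,0.02153823,0.3784,0.0134
73,male,0.02358865,0.3806,0.0131
74,male,0.02583891,0.3828,0.0128
75,male,0.02830849,0.385,0.0125
76,male,0.03101875,0.3872,0.0122
77,male,0.03399316,0.3894,0.0119
78,male,0.03725746,0.3916,0.0116
79,male,0.04083991,0.3938,0.0113
80,male,0.04477151,0.396,0.011
81,male,0.04908628,0.3982,0.0107
82,male,0.05382159,0.4004,0.0104
83,male,0.0590184,0.4026,0.0101
84,male,0.06472171,0.4048,0.0098
85,male,0.07098087,0.407,0.0095
86,male,0.07785005,0.4092,0.0092
87,male,0.08538872,0.4114,0.0089
88,male,0.09366213,0.4136,0.0086
89,male,0.10274187,0.4158,0.0083
90,male,0.11270654,0.418,0.008
91,male,0.12364238,0.4202,0.0077
92,male,0.13564405,0.4224,0.0074
93,male,0.14881543,0.4246,0.0071
94,male,0.1632705,0.4268,0.0068
95,male,0.1791344,0.429,0.0065
96,male,0.19654442,0.4312,0.0062
97,male,0.21565125,0.4334,0.0059
98,male,0.23662026,0.4356,0.0056
99,male,0.25963295,0.4378,0.0053
100,male,0.2848885,0.44,0.005
101,male,0.3126055,0.4422,0.005
102,male,0.34302384,0.4444,0.005
103,male,0.37640681,0.4466,0.005
104,male,0.41304334,0.4488,0.005
105,male,0.45325053,0.45,0.005
106,male,0.49737638,0.45,0.005
107,male,0.54580281,0.45,0.005
108,male,0.59894897,0.45,0.005
109,male,0.65727485,0.45,0.005
110,male,0.72128526,0.45,0.005
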