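sr_pmid,items_v1,items_v2,items_v3,gs_size,found_v1,found_v2,found_v3,se_v1,ppv_v1,f1_v1,se_v2,ppv_v2,f1_v2,se_v3,ppv_v3,f1_v3
33472813,297,294,147,30,27,27,24,0.900,0.091,0.165,0.900,0.092,0.167,0.800,0.163,0.271
33441384,4408,2265,901,16,14,13,11,0.875,0.003,0.006,0.812,0.006,0.011,0.688,0.012,0.024
33186535,145,153,1,6,4,4,1,0.667,0.028,0.053,0.667,0.026,0.050,0.167,1.000,0.286
33148618,9024,10000,3706,66,16,18,3,0.242,0.002,0.004,0.273,0.002,0.004,0.045,0.001,0.002
32909814,349,349,40,9,1,1,0,0.111,0.003,0.006,0.111,0.003,0.006,0.000,0.000,0.000
32496521,94,162,0,24,0,0,0,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
32459529,1950,812,1441,9,7,2,7,0.778,0.004,0.007,0.222,0.002,0.005,0.778,0.005,0.010
32442035,10000,10000,842,15,8,7,2,0.533,0.001,0.002,0.467,0.001,0.001,0.133,0.002,0.005
32371466,4185,3320,324,50,49,48,21,0.980,0.012,0.023,0.960,0.014,0.028,0.420,0.065,0.112
32199484,6347,6111,1231,128,0,0,0,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
31255301,1164,1023,456,61,41,35,34,0.672,0.035,0.067,0.574,0.034,0.065,0.557,0.075,0.132
30884526,770,716,30,79,0,0,0,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
30617123,1086,788,292,29,28,26,14,0.966,0.026,0.050,0.897,0.033,0.064,0.483,0.048,0.087
30326495,4360,2212,951,158,123,117,62,0.778,0.028,0.054,0.741,0.053,0.099,0.392,0.065,0.112
30158148,10000,2673,395,45,33,24,28,0.733,0.003,0.007,0.533,0.009,0.018,0.622,0.071,0.127
29049756,3155,2858,913,20,16,16,2,0.800,0.005,0.010,0.800,0.006,0.011,0.100,0.002,0.004
28903922,687,610,95,24,23,23,16,0.958,0.033,0.065,0.958,0.038,0.073,0.667,0.168,0.269
27893131,10000,10000,2439,48,34,33,27,0.708,0.003,0.007,0.688,0.003,0.007,0.562,0.011,0.022
27802505,2299,2227,195,21,19,19,14,0.905,0.008,0.016,0.905,0.009,0.017,0.667,0.072,0.130
27802478,3847,3525,2526,89,45,43,43,0.506,0.012,0.023,0.483,0.012,0.024,0.483,0.017,0.033
27548070,1634,910,626,26,20,10,9,0.769,0.012,0.024,0.385,0.011,0.021,0.346,0.014,0.028
27142267,10000,10000,10000,10,7,9,5,0.700,0.001,0.001,0.900,0.001,0.002,0.500,0.000,0.001
26903336,903,414,115,92,47,47,0,0.511,0.052,0.094,0.511,0.114,0.186,0.000,0.000,0.000
26349907,2675,265,1728,8,0,0,0,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
26199070,554,303,0,20,17,15,0,0.850,0.031,0.059,0.750,0.050,0.093,0.000,0.000,0.000
26109551,298,297,14,14,9,9,5,0.643,0.030,0.058,0.643,0.030,0.058,0.357,0.357,0.357
25770113,3046,2761,1956,7,7,5,7,1.000,0.002,0.005,0.714,0.002,0.004,1.000,0.004,0.007
25569206,746,691,0,49,49,49,0,1.000,0.066,0.123,1.000,0.071,0.132,0.000,0.000,0.000
25556126,212,206,50,9,8,8,4,0.889,0.038,0.072,0.889,0.039,0.074,0.444,0.080,0.136
25006006,834,395,407,25,24,23,20,0.960,0.029,0.056,0.920,0.058,0.110,0.800,0.049,0.093
24727842,2046,1989,0,69,66,66,0,0.957,0.032,0.062,0.957,0.033,0.064,0.000,0.000,0.000
24157497,10000,81,8636,61,61,0,61,1.000,0.006,0.012,0.000,0.000,0.000,1.000,0.007,0.014
24046285,978,978,812,12,12,12,12,1.000,0.012,0.024,1.000,0.012,0.024,1.000,0.015,0.029
23935058,628,20,887,5,3,0,1,0.600,0.005,0.009,0.000,0.000,0.000,0.200,0.001,0.002
23900314,499,300,195,6,5,5,4,0.833,0.010,0.020,0.833,0.017,0.033,0.667,0.021,0.040
23529983,283,160,0,8,8,2,0,1.000,0.028,0.055,0.250,0.013,0.024,0.000,0.000,0.000
23420235,6848,2305,3434,27,25,20,10,0.926,0.004,0.007,0.741,0.009,0.017,0.370,0.003,0.006
23033409,434,258,0,16,11,11,0,0.688,0.025,0.049,0.688,0.043,0.080,0.000,0.000,0.000
22986378,8633,7169,3884,40,26,38,19,0.650,0.003,0.006,0.950,0.005,0.011,0.475,0.005,0.010
22422870,1010,980,0,4,3,3,0,0.750,0.003,0.006,0.750,0.003,0.006,0.000,0.000,0.000
22323502,10000,10000,9784,5,3,3,2,0.600,0.000,0.001,0.600,0.000,0.001,0.400,0.000,0.000
22226047,1911,1239,1807,49,38,32,35,0.776,0.020,0.039,0.653,0.026,0.050,0.714,0.019,0.038
33176180,87,87,0,4,3,3,0,0.750,0.034,0.066,0.750,0.034,0.066,0.000,0.000,0.000
32479176,303,266,64,29,28,26,2,1.000,0.092,0.169,0.931,0.098,0.177,0.069,0.031,0.043
32427305,2035,2004,0,13,12,12,0,0.923,0.006,0.012,0.923,0.006,0.012,0.000,0.000,0.000
31727627,1884,1878,610,132,127,127,29,0.985,0.067,0.126,0.985,0.068,0.127,0.227,0.048,0.079
31585960,10000,10000,9514,227,186,206,139,0.819,0.019,0.036,0.907,0.021,0.040,0.612,0.015,0.029
30383109,4723,4716,570,38,36,36,2,0.947,0.008,0.015,0.947,0.008,0.015,0.053,0.004,0.007
28348110,27,27,0,24,1,1,0,0.042,0.037,0.039,0.042,0.037,0.039,0.000,0.000,0.000
28114600,85,35,25,68,9,3,0,0.132,0.106,0.118,0.044,0.086,0.058,0.000,0.000,0.000
26868137,10000,10000,10000,32,2,7,2,0.062,0.000,0.000,0.219,0.001,0.001,0.062,0.000,0.000
26830221,6167,1166,5102,76,74,28,72,0.974,0.012,0.024,0.368,0.024,0.045,0.947,0.014,0.028
26830055,6167,1166,5102,29,29,19,27,1.000,0.005,0.009,0.655,0.016,0.032,0.931,0.005,0.011
26420598,8405,8387,2421,57,47,47,30,0.825,0.006,0.011,0.825,0.006,0.011,0.526,0.012,0.024
26420387,8405,8387,2421,78,59,59,30,0.756,0.007,0.014,0.756,0.007,0.014,0.385,0.012,0.024
25059938,1524,1503,33,21,14,14,1,0.667,0.009,0.018,0.667,0.009,0.018,0.048,0.030,0.037
24592495,873,798,100,16,9,9,0,0.562,0.010,0.020,0.562,0.011,0.022,0.000,0.000,0.000
23460092,2426,2411,0,20,18,18,0,0.900,0.007,0.015,0.900,0.007,0.015,0.000,0.000,0.000
22777524,4645,3048,2838,37,37,35,31,1.000,0.008,0.016,0.946,0.011,0.023,0.838,0.011,0.022
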