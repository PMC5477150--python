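compound,col1,col2,col3,col4,col5,col6,col7,col8,col9,col10,col11,col12,col13,col14,col15,col16,col17,col18,col19,col20,col21,col22,col23,col24,col25,col26,col27,col28,col29,col30,col1_sd,col2_sd,col3_sd,col4_sd,col5_sd,col6_sd,col7_sd,col8_sd,col9_sd,col10_sd,col11_sd,col12_sd,col13_sd,col14_sd,col15_sd,col16_sd,col17_sd,col18_sd,col19_sd,col20_sd,col21_sd,col22_sd,col23_sd,col24_sd,col25_sd,col26_sd,col27_sd,col28_sd,col29_sd,col30_sd
Chonglou saponin VII,21.234,16.555,21.101,21.014,22.132,21.276,20.760,16.551,17.225,20.856,21.016,21.300,21.076,17.201,21.652,17.501,21.452,19.669,20.092,18.684,18.438,22.082,16.769,19.296,19.732,19.015,23.492,20.609,17.970,18.348,0.021,0.010,0.004,0.011,0.009,0.012,0.018,0.008,0.006,0.008,0.015,0.014,0.012,0.022,0.013,0.006,0.013,0.010,0.013,0.006,0.015,0.021,0.007,0.016,0.017,0.007,0.247,0.003,0.007,0.012
Chonglou saponin VI,23.001,17.989,23.070,22.898,24.502,23.693,23.362,18.865,19.640,23.752,22.076,23.756,23.828,19.731,24.065,19.571,23.735,21.583,22.560,21.334,20.986,25.078,19.154,22.819,22.099,21.059,25.839,22.574,20.468,20.209,0.006,0.006,0.027,0.018,0.004,0.016,0.008,0.023,0.005,0.021,0.016,0.007,0.004,0.003,0.024,0.018,0.006,0.022,0.010,0.021,0.010,0.005,0.008,0.004,0.018,0.014,0.250,0.005,0.011,0.017
Chonglou saponin II,32.773,27.161,32.483,32.679,33.176,32.618,30.941,25.923,26.754,31.687,32.470,31.599,31.627,27.525,32.375,27.401,32.747,30.361,29.568,28.580,28.085,32.475,26.240,31.192,29.535,29.401,34.884,30.806,27.287,29.233,0.007,0.011,0.021,0.032,0.017,0.006,0.011,0.016,0.013,0.011,0.023,0.003,0.006,0.009,0.010,0.004,0.019,0.007,0.006,0.008,0.008,0.020,0.011,0.019,0.004,0.002,0.344,0.003,0.031,0.011
Chonglou saponin I,35.118,29.154,34.963,35.170,35.936,35.929,33.813,28.310,29.471,34.872,35.476,34.337,34.695,30.504,35.197,29.826,35.513,32.657,32.218,31.385,30.849,35.721,28.935,34.710,32.153,31.845,37.637,32.783,29.985,31.893,0.004,0.002,0.006,0.036,0.003,0.007,0.003,0.011,0.005,0.004,0.010,0.015,0.001,0.005,0.006,0.010,0.011,0.005,0.005,0.004,0.007,0.023,0.004,0.009,0.021,0.001,0.330,0.002,0.007,0.014
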