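analyte_code,alt_units_flag,pre_mean,pre_sd,h24_mean,h24_sd,wk2_mean,wk2_sd,mo3_mean,mo3_sd,mo6_mean,mo6_sd,mo9_mean,mo9_sd,mo12_min,mo12_max
Pse,0,36.76,24.90,31.09,22.63,42.35,30.23,41.42,27.47,43.02,16.37,47.17,39.66,19.87,27.43
U,0,0.20,0.14,0.22,0.18,0.21,0.16,0.21,0.14,0.27,0.14,0.16,0.08,0.08,0.11
Ino,0,0.16,0.12,0.23,0.22,0.21,0.20,0.14,0.14,0.16,0.10,0.24,0.24,0.12,0.15
3mU,0,0.21,0.14,0.15,0.11,0.21,0.11,0.24,0.12,0.23,0.10,0.22,0.12,0.12,0.15
2dG,1,1.70,1.38,1.09,1.08,2.00,1.78,1.25,0.77,1.40,0.91,1.39,0.85,0.51,1.03
2mG,0,0.78,0.54,0.51,0.34,0.71,0.44,1.00,0.86,0.93,0.55,1.01,0.49,0.44,0.50
8OH2dG,1,2.53,1.39,1.65,1.22,2.94,1.64,3.34,2.22,3.56,1.44,3.10,2.55,1.53,1.78
6mA,0,0.012,0.011,0.028,0.073,0.024,0.036,0.027,0.046,0.011,0.007,0.008,0.004,0.005,0.007
22dmG,0,2.11,1.37,1.68,0.93,2.00,0.86,2.30,1.03,2.59,0.82,2.12,1.05,1.44,1.48
5-MTA,1,0.08,0.06,0.08,0.12,0.12,0.14,0.11,0.09,0.06,0.03,0.07,0.06,0.03,0.06
MTA,0,0.47,0.42,0.20,0.20,0.61,0.55,0.72,0.66,0.56,0.50,0.92,0.91,0.55,0.90
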