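analyte_code,range_low_uM,range_high_uM,weighting,slope,sd_slope,ci95_slope_low,ci95_slope_high,intercept,sd_intercept,ci95_intercept_low,ci95_intercept_high,correlation_r,sxy,lod_uM,loq_uM,intercept_ci_duplicates_slope_ci
Pse,2.5,250,1/y,0.08,0.001,0.074,0.079,0.008,0.012,-0.016,0.033,0.996,0.043,0.510,1.546,0
U,0.05,5,1/y,0.29,0.004,0.280,0.295,0.0012,0.0009,-0.0006,0.003,0.996,0.003,0.001,0.030,0
Ino,0.05,5,1/y,1.03,0.017,0.995,1.068,0.011,0.004,0.002,0.020,0.995,0.013,0.013,0.040,0
3mU,0.05,5,1/y,0.97,0.009,0.951,0.990,0.004,0.002,-0.0007,0.008,0.998,0.008,0.007,0.022,0
2dG,0.001,0.1,1/x,2.89,0.066,2.745,3.032,0.001,0.0003,2.745,3.032,0.993,0.0008,0.0004,0.001,1
2mG,0.1,10,1/y,0.54,0.008,0.521,0.555,0.011,0.004,0.003,0.019,0.996,0.012,0.023,0.070,0
8OH2dG,0.0025,0.25,1/x,2.14,0.046,2.043,2.232,-0.0005,0.0005,-0.002,0.0006,0.990,0.002,0.0008,0.0025,0
6mA,0.005,0.5,1/y,7.12,0.131,6.849,7.399,0.006,0.003,5.106e-06,0.013,0.993,0.010,0.001,0.004,0
22dmG,0.25,25,1/y,0.48,0.006,0.470,0.498,0.055,0.008,0.037,0.072,0.998,0.021,0.053,0.162,0
5-MTA,0.025,2.5,1/y,11.80,0.171,11.440,12.150,0.047,0.020,0.005,0.089,0.996,0.066,0.006,0.017,0
MTA,0.00025,0.025,1/x,15.22,0.368,14.450,15.980,0.0006,0.0004,-0.0003,0.002,0.987,0.001,0.00009,0.00025,0
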