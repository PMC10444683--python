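analyte_code,level,nominal_uM,intra_accuracy_pct,intra_cv_pct,inter_accuracy_pct,inter_cv_pct,recovery_pct,matrix_effect_cv_pct
22dmG,LLOQ,0.25,95.99,9.00,95.26,8.98,,
22dmG,LQC,1.25,107.40,1.02,109.39,2.88,89.38,7.98
22dmG,MQC,5,104.59,3.21,106.52,3.98,96.01,
22dmG,HQC,10,98.90,2.89,103.59,5.37,87.98,12.24
2dG,LLOQ,0.001,98.25,8.69,98.29,6.83,,
2dG,LQC,0.005,99.61,6.89,102.64,5.56,89.87,9.55
2dG,MQC,0.02,96.47,4.57,99.67,5.14,95.75,
2dG,HQC,0.04,92.45,2.83,98.89,5.96,87.32,13.73
5-MTA,LLOQ,0.025,95.36,6.39,95.91,8.17,,
5-MTA,LQC,0.125,97.18,2.70,105.50,5.71,89.16,8.47
5-MTA,MQC,0.5,105.93,3.88,107.89,3.90,95.46,
5-MTA,HQC,1,99.74,3.53,103.13,3.41,86.67,13.52
8OH2dG,LLOQ,0.0025,101.83,7.12,101.88,10.49,,
8OH2dG,LQC,0.0125,94.06,4.21,93.08,8.88,68.50,9.76
8OH2dG,MQC,0.05,96.25,6.07,99.94,6.75,79.08,
8OH2dG,HQC,0.1,93.64,4.48,97.43,8.21,76.35,11.17
Ino,LLOQ,0.05,97.96,6.07,98.75,6.68,,
Ino,LQC,0.25,101.59,1.89,103.87,3.39,87.52,9.99
Ino,MQC,1,98.48,3.56,102.52,4.77,97.35,
Ino,HQC,2,95.52,2.63,101.86,6.43,84.52,14.28
6mA,LLOQ,0.005,95.20,8.36,99.08,8.86,,
6mA,LQC,0.025,103.26,3.83,106.83,5.73,90.82,8.48
6mA,MQC,0.1,108.41,2.23,109.31,2.81,95.42,
6mA,HQC,0.2,103.22,2.58,105.17,2.47,87.86,11.36
2mG,LLOQ,0.1,95.04,9.26,95.69,7.99,,
2mG,LQC,0.5,102.62,1.34,107.34,3.87,89.04,7.96
2mG,MQC,2,100.43,2.80,105.94,4.76,96.48,
2mG,HQC,4,97.22,3.04,103.47,5.59,88.45,11.17
MTA,LLOQ,0.00025,99.97,8.09,98.95,8.51,,
MTA,LQC,0.00125,104.48,2.89,104.01,4.48,92.24,5.72
MTA,MQC,0.005,103.18,4.53,102.33,5.00,95.95,
MTA,HQC,0.01,101.23,2.56,102.01,2.63,87.13,11.47
3mU,LLOQ,0.05,99.30,6.78,100.56,6.75,,
3mU,LQC,0.25,101.54,1.42,102.31,3.24,87.86,10.45
3mU,MQC,1,98.21,3.75,100.80,4.48,96.67,
3mU,HQC,2,95.54,3.33,100.86,6.42,84.92,14.96
Pse,LLOQ,2.5,96.20,9.01,96.36,7.76,,
Pse,LQC,12.5,106.52,0.59,108.51,5.19,87.15,9.74
Pse,MQC,50,102.54,2.88,106.43,4.23,95.97,
Pse,HQC,100,96.88,3.34,105.73,9.81,85.67,12.48
U,LLOQ,0.05,99.32,7.87,99.23,8.08,,
U,LQC,0.25,103.78,2.09,103.45,5.22,85.68,10.04
U,MQC,1,99.23,2.97,101.81,4.32,97.32,
U,HQC,2,96.17,3.34,102.68,6.97,82.72,14.21
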