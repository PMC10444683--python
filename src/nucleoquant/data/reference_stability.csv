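analyte_code,level,nominal_uM,condition,label,pct_of_nominal
22dmG,LQC,1.25,bench_top,3h,111.04
22dmG,LQC,1.25,bench_top,6h,112.32
22dmG,LQC,1.25,autosampler,0h,106.59
22dmG,LQC,1.25,autosampler,25h,104.85
22dmG,LQC,1.25,autosampler,50h,104.60
22dmG,LQC,1.25,freeze_thaw,cycle0,115.12
22dmG,LQC,1.25,freeze_thaw,cycle1,121.86
22dmG,LQC,1.25,freeze_thaw,cycle2,116.41
22dmG,LQC,1.25,freeze_thaw,cycle3,114.51
22dmG,HQC,10,bench_top,3h,104.25
22dmG,HQC,10,bench_top,6h,93.21
22dmG,HQC,10,autosampler,0h,102.67
22dmG,HQC,10,autosampler,25h,102.52
22dmG,HQC,10,autosampler,50h,103.22
22dmG,HQC,10,freeze_thaw,cycle0,106.13
22dmG,HQC,10,freeze_thaw,cycle1,112.25
22dmG,HQC,10,freeze_thaw,cycle2,110.97
22dmG,HQC,10,freeze_thaw,cycle3,112.81
2dG,LQC,0.005,bench_top,3h,103.90
2dG,LQC,0.005,bench_top,6h,101.02
2dG,LQC,0.005,autosampler,0h,91.55
2dG,LQC,0.005,autosampler,25h,94.37
2dG,LQC,0.005,autosampler,50h,99.02
2dG,LQC,0.005,freeze_thaw,cycle0,110.78
2dG,LQC,0.005,freeze_thaw,cycle1,110.58
2dG,LQC,0.005,freeze_thaw,cycle2,111.47
2dG,LQC,0.005,freeze_thaw,cycle3,111.24
2dG,HQC,0.04,bench_top,3h,96.02
2dG,HQC,0.04,bench_top,6h,86.21
2dG,HQC,0.04,autosampler,0h,92.98
2dG,HQC,0.04,autosampler,25h,92.23
2dG,HQC,0.04,autosampler,50h,90.21
2dG,HQC,0.04,freeze_thaw,cycle0,107.97
2dG,HQC,0.04,freeze_thaw,cycle1,113.71
2dG,HQC,0.04,freeze_thaw,cycle2,107.61
2dG,HQC,0.04,freeze_thaw,cycle3,107.49
5-MTA,LQC,0.125,bench_top,3h,104.66
5-MTA,LQC,0.125,bench_top,6h,104.24
5-MTA,LQC,0.125,autosampler,0h,96.08
5-MTA,LQC,0.125,autosampler,25h,91.90
5-MTA,LQC,0.125,autosampler,50h,91.48
5-MTA,LQC,0.125,freeze_thaw,cycle0,107.93
5-MTA,LQC,0.125,freeze_thaw,cycle1,111.57
5-MTA,LQC,0.125,freeze_thaw,cycle2,107.10
5-MTA,LQC,0.125,freeze_thaw,cycle3,106.40
5-MTA,HQC,1,bench_top,3h,101.25
5-MTA,HQC,1,bench_top,6h,91.49
5-MTA,HQC,1,autosampler,0h,95.99
5-MTA,HQC,1,autosampler,25h,93.62
5-MTA,HQC,1,autosampler,50h,93.89
5-MTA,HQC,1,freeze_thaw,cycle0,99.63
5-MTA,HQC,1,freeze_thaw,cycle1,107.99
5-MTA,HQC,1,freeze_thaw,cycle2,104.46
5-MTA,HQC,1,freeze_thaw,cycle3,105.93
8OH2dG,LQC,0.0125,bench_top,3h,113.00
8OH2dG,LQC,0.0125,bench_top,6h,108.07
8OH2dG,LQC,0.0125,autosampler,0h,112.74
8OH2dG,LQC,0.0125,autosampler,25h,106.89
8OH2dG,LQC,0.0125,autosampler,50h,107.72
8OH2dG,LQC,0.0125,freeze_thaw,cycle0,97.03
8OH2dG,LQC,0.0125,freeze_thaw,cycle1,105.46
8OH2dG,LQC,0.0125,freeze_thaw,cycle2,110.94
8OH2dG,LQC,0.0125,freeze_thaw,cycle3,114.06
8OH2dG,HQC,0.1,bench_top,3h,101.58
8OH2dG,HQC,0.1,bench_top,6h,92.51
8OH2dG,HQC,0.1,autosampler,0h,103.13
8OH2dG,HQC,0.1,autosampler,25h,106.62
8OH2dG,HQC,0.1,autosampler,50h,103.65
8OH2dG,HQC,0.1,freeze_thaw,cycle0,93.20
8OH2dG,HQC,0.1,freeze_thaw,cycle1,89.57
8OH2dG,HQC,0.1,freeze_thaw,cycle2,100.32
8OH2dG,HQC,0.1,freeze_thaw,cycle3,106.97
Ino,LQC,0.25,bench_top,3h,107.85
Ino,LQC,0.25,bench_top,6h,108.22
Ino,LQC,0.25,autosampler,0h,107.18
Ino,LQC,0.25,autosampler,25h,105.20
Ino,LQC,0.25,autosampler,50h,109.96
Ino,LQC,0.25,freeze_thaw,cycle0,114.87
Ino,LQC,0.25,freeze_thaw,cycle1,115.14
Ino,LQC,0.25,freeze_thaw,cycle2,112.41
Ino,LQC,0.25,freeze_thaw,cycle3,113.30
Ino,HQC,2,bench_top,3h,101.67
Ino,HQC,2,bench_top,6h,91.20
Ino,HQC,2,autosampler,0h,107.80
Ino,HQC,2,autosampler,25h,108.37
Ino,HQC,2,autosampler,50h,108.55
Ino,HQC,2,freeze_thaw,cycle0,111.93
Ino,HQC,2,freeze_thaw,cycle1,112.07
Ino,HQC,2,freeze_thaw,cycle2,107.81
Ino,HQC,2,freeze_thaw,cycle3,112.32
6mA,LQC,0.025,bench_top,3h,107.54
6mA,LQC,0.025,bench_top,6h,106.93
6mA,LQC,0.025,autosampler,0h,97.70
6mA,LQC,0.025,autosampler,25h,92.10
6mA,LQC,0.025,autosampler,50h,88.91
6mA,LQC,0.025,freeze_thaw,cycle0,106.34
6mA,LQC,0.025,freeze_thaw,cycle1,114.34
6mA,LQC,0.025,freeze_thaw,cycle2,115.82
6mA,LQC,0.025,freeze_thaw,cycle3,113.13
6mA,HQC,0.2,bench_top,3h,103.56
6mA,HQC,0.2,bench_top,6h,94.41
6mA,HQC,0.2,autosampler,0h,93.67
6mA,HQC,0.2,autosampler,25h,89.46
6mA,HQC,0.2,autosampler,50h,88.22
6mA,HQC,0.2,freeze_thaw,cycle0,98.13
6mA,HQC,0.2,freeze_thaw,cycle1,114.44
6mA,HQC,0.2,freeze_thaw,cycle2,108.34
6mA,HQC,0.2,freeze_thaw,cycle3,104.99
2mG,LQC,0.5,bench_top,3h,112.89
2mG,LQC,0.5,bench_top,6h,108.82
2mG,LQC,0.5,autosampler,0h,108.20
2mG,LQC,0.5,autosampler,25h,106.51
2mG,LQC,0.5,autosampler,50h,104.44
2mG,LQC,0.5,freeze_thaw,cycle0,114.75
2mG,LQC,0.5,freeze_thaw,cycle1,115.87
2mG,LQC,0.5,freeze_thaw,cycle2,116.39
2mG,LQC,0.5,freeze_thaw,cycle3,111.50
2mG,HQC,4,bench_top,3h,102.58
2mG,HQC,4,bench_top,6h,91.13
2mG,HQC,4,autosampler,0h,101.06
2mG,HQC,4,autosampler,25h,100.60
2mG,HQC,4,autosampler,50h,100.43
2mG,HQC,4,freeze_thaw,cycle0,108.75
2mG,HQC,4,freeze_thaw,cycle1,113.85
2mG,HQC,4,freeze_thaw,cycle2,110.30
2mG,HQC,4,freeze_thaw,cycle3,109.14
MTA,LQC,0.00125,bench_top,3h,102.35
MTA,LQC,0.00125,bench_top,6h,98.17
MTA,LQC,0.00125,autosampler,0h,101.00
MTA,LQC,0.00125,autosampler,25h,99.67
MTA,LQC,0.00125,autosampler,50h,103.43
MTA,LQC,0.00125,freeze_thaw,cycle0,92.85
MTA,LQC,0.00125,freeze_thaw,cycle1,111.82
MTA,LQC,0.00125,freeze_thaw,cycle2,114.48
MTA,LQC,0.00125,freeze_thaw,cycle3,109.86
MTA,HQC,0.01,bench_top,3h,104.0
MTA,HQC,0.01,bench_top,6h,92.01
MTA,HQC,0.01,autosampler,0h,90.03
MTA,HQC,0.01,autosampler,25h,97.67
MTA,HQC,0.01,autosampler,50h,104.10
MTA,HQC,0.01,freeze_thaw,cycle0,91.76
MTA,HQC,0.01,freeze_thaw,cycle1,112.14
MTA,HQC,0.01,freeze_thaw,cycle2,112.88
MTA,HQC,0.01,freeze_thaw,cycle3,98.68
3mU,LQC,0.25,bench_top,3h,106.20
3mU,LQC,0.25,bench_top,6h,100.70
3mU,LQC,0.25,autosampler,0h,105.41
3mU,LQC,0.25,autosampler,25h,106.82
3mU,LQC,0.25,autosampler,50h,108.29
3mU,LQC,0.25,freeze_thaw,cycle0,114.33
3mU,LQC,0.25,freeze_thaw,cycle1,112.91
3mU,LQC,0.25,freeze_thaw,cycle2,114.86
3mU,LQC,0.25,freeze_thaw,cycle3,113.48
3mU,HQC,2,bench_top,3h,95.56
3mU,HQC,2,bench_top,6h,90.04
3mU,HQC,2,autosampler,0h,105.51
3mU,HQC,2,autosampler,25h,99.78
3mU,HQC,2,autosampler,50h,100.32
3mU,HQC,2,freeze_thaw,cycle0,108.13
3mU,HQC,2,freeze_thaw,cycle1,112.91
3mU,HQC,2,freeze_thaw,cycle2,103.97
3mU,HQC,2,freeze_thaw,cycle3,109.38
Pse,LQC,12.5,bench_top,3h,107.69
Pse,LQC,12.5,bench_top,6h,105.75
Pse,LQC,12.5,autosampler,0h,105.39
Pse,LQC,12.5,autosampler,25h,107.19
Pse,LQC,12.5,autosampler,50h,107.60
Pse,LQC,12.5,freeze_thaw,cycle0,108.24
Pse,LQC,12.5,freeze_thaw,cycle1,115.87
Pse,LQC,12.5,freeze_thaw,cycle2,115.83
Pse,LQC,12.5,freeze_thaw,cycle3,114.11
Pse,HQC,100,bench_top,3h,95.01
Pse,HQC,100,bench_top,6h,86.41
Pse,HQC,100,autosampler,0h,90.13
Pse,HQC,100,autosampler,25h,95.42
Pse,HQC,100,autosampler,50h,95.52
Pse,HQC,100,freeze_thaw,cycle0,96.86
Pse,HQC,100,freeze_thaw,cycle1,103.64
Pse,HQC,100,freeze_thaw,cycle2,102.35
Pse,HQC,100,freeze_thaw,cycle3,106.32
U,LQC,0.25,bench_top,3h,108.85
U,LQC,0.25,bench_top,6h,108.05
U,LQC,0.25,autosampler,0h,107.51
U,LQC,0.25,autosampler,25h,107.78
U,LQC,0.25,autosampler,50h,107.39
U,LQC,0.25,freeze_thaw,cycle0,111.92
U,LQC,0.25,freeze_thaw,cycle1,114.42
U,LQC,0.25,freeze_thaw,cycle2,115.20
U,LQC,0.25,freeze_thaw,cycle3,112.28
U,HQC,2,bench_top,3h,101.46
U,HQC,2,bench_top,6h,92.43
U,HQC,2,autosampler,0h,99.02
U,HQC,2,autosampler,25h,101.75
U,HQC,2,autosampler,50h,104.23
U,HQC,2,freeze_thaw,cycle0,106.39
U,HQC,2,freeze_thaw,cycle1,113.70
U,HQC,2,freeze_thaw,cycle2,108.05
U,HQC,2,freeze_thaw,cycle3,111.31
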