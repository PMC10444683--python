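analyte_code,display_name,retention_time_min,precursor_mz,quantifier_mz,qualifier_mz,ce_quant_v,ce_qual_v,fragmentor_v,expected_ion_ratio_pct,ion_ratio_low_pct,ion_ratio_high_pct
Pse,Pse,1.9,245,191,167,20,10,90,17.1,14.0,20.9
U,U,2.6,245,113,70,10,35,70,12.4,9.0,13.6
Ino,Ino,4.3,269,137,119,10,40,80,9.3,7.6,11.4
3mU,3mU,5.9,259,127,96,5,40,80,17.8,14.2,21.3
2dG,2dG,6.7,268,152,135,10,40,80,35.8,29.7,44.6
2mG,2mG,8.0,298,166,149,40,20,90,86.5,67.9,101.8
8OH2dG,8OH2dG,9.5,284,168,140,10,35,80,31.1,23.2,34.8
6mA,6mA,9.9,282,150,123,40,40,110,14.0,11.1,16.7
22dmG,"2,2dmG",11.3,312,110,135,30,40,80,8.8,6.9,10.3
8BrG,8BrG (IS),11.7,362,230,213,20,40,100,,,
5-MTA,5-MTA,14.3,298,136,119,20,40,90,8.1,6.3,9.5
MTA,MTA,16.7,314,182,134,20,40,80,51.2,39.0,58.4
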