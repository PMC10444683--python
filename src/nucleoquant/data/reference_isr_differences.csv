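sample_id,Pse,U,Ino,3mU,2dG,2mG,8OH2dG,6mA,22dmG,5-MTA,MTA
P5,20.1,20.5,20.0,34.6,18.9,19.9,9.9,17.2,8.5,16.5,11.4
P15,1.4,13.3,5.2,13.7,9.8,19.5,18.8,14.6,15.0,19.2,15.3
P24,19.9,17.0,19.6,20.1,19.3,4.3,19.9,19.4,3.1,14.0,11.2
P26,12.3,17.7,14.5,18.3,10.6,3.9,18.9,16.0,8.2,19.4,12.2
P28,3.0,3.6,7.5,20.3,12.1,22.2,18.9,1.4,18.7,2.8,5.1
P38,14.7,20.0,17.5,19.0,13.1,14.5,5.1,16.5,5.6,19.7,13.8
P42,10.5,15.1,17.8,19.0,14.8,17.7,12.7,19.7,19.5,15.5,13.0
P43,11.9,5.9,8.5,18.7,19.3,11.3,19.8,18.2,16.6,2.7,11.3
P45,4.3,5.3,13.0,17.6,6.3,3.9,10.8,15.5,5.1,1.3,18.2
P46,7.5,10.3,4.3,19.1,9.6,15.0,15.6,20.5,1.3,5.5,6.4
P57,19.8,18.7,10.7,16.0,15.1,5.6,15.1,18.9,3.7,0.1,8.7
P67,16.8,19.4,4.9,19.2,17.1,4.6,16.3,14.3,0.8,11.3,3.4
P73,17.5,13.2,17.1,20.0,4.9,17.6,15.8,23.4,3.4,9.3,15.2
P74,19.9,19.9,17.4,16.5,19.2,9.5,17.6,19.8,5.0,16.0,19.1
P82,15.4,16.3,18.7,18.6,12.2,12.0,10.1,18.6,1.7,4.8,1.5
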