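api,polymer,ai25,ai40,ai_mean,delta_ecoul,d,rmsf
FLA,EEC,100,100,87,-698.7,1.20,0.082
FLA,PAA,25,13,13,4863.8,0.42,0.068
FLA,PSA,0,0,15,1948.8,0.54,0.078
FLA,PVP,100,100,87,-3753.7,0.49,0.080
PAC,EEC,25,13,13,-704.0,3.73,0.0892
PAC,PAA,100,100,67,1945.4,1.51,0.0724
PAC,PSA,100,100,78,-1468.4,2.06,0.0790
PAC,PVP,100,94,49,-2590.1,1.25,0.0721
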