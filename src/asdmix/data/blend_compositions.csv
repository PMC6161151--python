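polymer,n_chains,monomers_per_chain,api,n_api,total_mass_amu,w_api_percent,volume_nm3
EEC,14,40,FLA,95,108631,24.6,161.0
PAA,28,40,FLA,95,107486,24.9,133.8
PSA,12,40,FLA,95,99774,23.2,139.2
PVP,18,40,FLA,95,106778,25.0,152.0
EEC,14,40,FLA,190,135348,39.5,193.5
PAA,28,40,FLA,190,134203,39.8,166.5
PSA,12,40,FLA,190,126491,37.7,171.4
PVP,18,40,FLA,190,133495,40.0,184.1
EEC,14,40,PAC,149,108617,24.6,167.5
PAA,28,40,PAC,149,107472,24.8,140.2
PSA,12,40,PAC,149,99761,23.2,144.9
PVP,18,40,PAC,149,106764,25.0,157.0
EEC,14,40,PAC,298,135321,39.5,206.3
PAA,28,40,PAC,298,134176,39.8,179.5
PSA,12,40,PAC,298,126464,37.6,183.6
PVP,18,40,PAC,298,133468,40.0,195.7
EEC,14,40,,0,81913,0.0,128.7
PAA,28,40,,0,80769,0.0,100.2
PSA,12,40,,0,88446,0.0,107.3
PVP,18,40,,0,80061,0.0,120.1
,0,0,FLA,302,84933,100.0,104.9
,0,0,PAC,475,85130,100.0,128.0
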