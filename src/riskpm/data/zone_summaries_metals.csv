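zone,species,mean_ng_m3,sd_ng_m3,n_days
North,Al,1423.40,254.60,79
North,Cr(VI),104.16,66.28,79
North,Mn,28.39,20.41,79
North,Cu,33.75,17.52,79
North,Zn,57.99,16.31,79
North,As,44.92,68.95,79
North,Pb,27.13,40.25,79
South,Al,1420.90,248.11,52
South,Cr(VI),64.08,5.74,52
South,Mn,14.56,5.57,52
South,Cu,26.48,13.12,52
South,Zn,53.60,9.97,52
South,As,13.99,15.42,52
South,Pb,10.97,22.14,52
Populated,Al,1658.94,185.82,79
Populated,Cr(VI),66.03,5.78,79
Populated,Mn,16.90,6.35,79
Populated,Cu,30.07,23.83,79
Populated,Zn,55.85,12.87,79
Populated,As,13.87,15.08,79
Populated,Pb,26.23,34.71,79
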