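zone,species,mean_ng_m3,sd_ng_m3,n_days
North,Nap,0.03,0.01,79
North,Acy,0.41,0.07,79
North,Ace,0.50,0.10,79
North,Flu,0.45,0.12,79
North,Phe,0.52,0.12,79
North,Ant,0.47,0.10,79
North,FR,0.47,0.10,79
North,Pyr,0.52,0.15,79
North,BaA,0.72,0.16,79
North,Tri,0.47,0.07,79
North,IDP,2.00,0.48,79
North,BbF,0.64,0.15,79
North,BaP,0.49,0.21,79
North,BkF,0.71,0.22,79
South,Nap,0.04,0.01,52
South,Acy,0.44,0.06,52
South,Ace,0.62,0.09,52
South,Flu,0.54,0.14,52
South,Phe,0.64,0.09,52
South,Ant,0.49,0.08,52
South,FR,0.64,0.15,52
South,Pyr,0.63,0.13,52
South,BaA,0.91,0.20,52
South,Tri,0.48,0.13,52
South,IDP,2.83,0.63,52
South,BbF,0.85,0.26,52
South,BaP,0.60,0.17,52
South,BkF,0.69,0.23,52
Populated,Nap,0.03,0.01,79
Populated,Acy,0.30,0.10,79
Populated,Ace,0.40,0.14,79
Populated,Flu,0.37,0.14,79
Populated,Phe,0.37,0.15,79
Populated,Ant,0.36,0.11,79
Populated,FR,0.40,0.10,79
Populated,Pyr,0.42,0.12,79
Populated,BaA,0.59,0.14,79
Populated,Tri,0.40,0.12,79
Populated,IDP,1.99,0.63,79
Populated,BbF,0.58,0.13,79
Populated,BaP,0.41,0.15,79
Populated,BkF,0.58,0.20,79
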