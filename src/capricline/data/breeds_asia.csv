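breed_id,breed_name,country,subregion,lon,lat,n,ho,he,fst_vs_ref,fis,f_roh,distance_km
ANK,Ankara,Turkey,West Asia,31.96,39.97,18,0.415,0.411,0.043,-0.00878,,1514.1681
KIL,Kil,Turkey,West Asia,36.62,40.47,23,0.422,0.416,0.037,-0.01705,,1180.8027
KLS,Kilis,Turkey,West Asia,37.12,36.72,36,0.417,0.415,0.033,-0.00422,,977.4969
IRA_KUR,Markhoz,Iran,West Asia,46.98,35.32,50,0.41,0.404,,0.05374,,124.337
BAB,Barbari,Pakistan,West Asia,72.48,30.3,16,0.387,0.363,0.116,-0.06887,,2389.8577
BRI,Bari,Pakistan,West Asia,68.86,26.08,25,0.346,0.361,0.086,0.04327,,2244.915
BUT,Bugituri,Pakistan,West Asia,68.86,26.08,31,0.355,0.36,0.081,0.01441,,2244.915
DDP,Dera Din Panah,Pakistan,West Asia,72.48,30.3,20,0.36,0.367,0.08,0.01994,,2389.8577
KAC,Kachan,Pakistan,West Asia,68.86,26.08,19,0.359,0.359,0.116,0.00062,,2244.915
KAM,Kamori,Pakistan,West Asia,68.86,26.08,38,0.358,0.352,0.102,-0.01718,,2244.915
LOH,Lohri,Pakistan,West Asia,68.86,26.08,17,0.386,0.371,0.077,-0.04128,,2244.915
PAH,Pahari,Pakistan,West Asia,72.48,30.3,19,0.396,0.386,0.057,-0.02704,,2389.8577
PAT,Pateri,Pakistan,West Asia,68.86,26.08,27,0.367,0.368,0.068,0.00478,,2244.915
TAP,Tapri,Pakistan,West Asia,68.36,25.47,22,0.368,0.376,0.067,0.02208,,2235.0932
TED,Teddi,Pakistan,West Asia,72.48,30.3,47,0.372,0.372,0.069,0.00155,,2389.8577
THA,Thari,Pakistan,West Asia,68.86,26.08,16,0.394,0.39,0.05,-0.01262,,2244.915
NJ,Nanjiang,China,East Asia,82.63,40.7,23,0.39,0.384,0.059,-0.01778,,3167.4685
QG,Qinggeda,China,East Asia,88.23,43.29,24,0.406,0.403,0.038,-0.00749,,3640.5662
AC,Aarbas Cashmere,China,East Asia,108.09,38.79,59,0.382,0.374,0.069,-0.02258,,5351.9616
JN,Jining Grey,China,East Asia,116.27,35.25,39,0.413,0.408,0.049,-0.01356,,6163.9232
LP,Luoping Yellow,China,East Asia,104.45,25.05,24,0.352,0.356,0.116,0.01168,,5538.9409
GF,Guangfeng,China,East Asia,118.23,28.32,24,0.341,0.362,0.094,0.06049,,6633.596
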