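breed_id,breed_name,country,subregion,lon,lat,n,ho,he,fst_vs_ref,fis,f_roh,distance_km
LNR_DK,Landrace Goat,Denmark,Northern Europe,11.44,55.56,50,0.376,0.391,0.077,0.03887,,3631.118
LNR_FI,Landrace Goat,Finland,Northern Europe,22.56,62.77,20,0.382,0.384,0.094,0.00353,,3613.356
LNR_NL,Landrace Goat,Netherlands,Northern Europe,5.12,52.09,15,0.376,0.364,0.131,-0.0349,,3894.742
ENG,Old English Goat,United Kingdom,British-Irish Isles,-3.44,55.38,32,0.286,0.317,0.126,0.20061,,4521.19
CRS,Corse,France,Western Europe,9.0,42.19,29,0.407,0.409,0.056,0.00248,,3449.975
FSS,Fosses,France,Western Europe,-1.12,47.97,24,0.398,0.4,0.068,0.00561,,4273.52
PTV,Poitevine,France,Western Europe,0.35,46.5,27,0.387,0.387,0.085,-0.00197,,4155.932
PVC,Provençale,France,Western Europe,4.01,46.28,17,0.418,0.407,0.065,-0.02903,,3873.527
PYR,Pyrenean,France,Western Europe,0.52,43.33,26,0.387,0.395,0.075,0.02034,,4143.577
IRL,Old Irish Goat,Ireland,British-Irish Isles,-8.24,53.41,50,0.346,0.374,0.078,0.06665,,4807.525
ARG,Argentata,Italy,Southern Europe,15.13,38.02,24,0.423,0.419,0.045,-0.01119,,2925.661
ASP,Aspromontana,Italy,Southern Europe,15.91,37.99,23,0.409,0.413,0.051,0.01052,,2857.277
BIO,Bionda dell'Adamello,Italy,Southern Europe,10.36,46.03,24,0.411,0.411,0.052,-0.00112,,3383.35
CCG,Ciociara Grigia,Italy,Southern Europe,13.82,41.61,16,0.406,0.417,0.049,0.02655,,3047.132
DIT,Di Teramo,Italy,Southern Europe,13.37,42.38,19,0.405,0.383,0.092,-0.05974,,3091.671
GAR,Garganica,Italy,Southern Europe,15.57,40.7,15,0.424,0.395,0.075,-0.07653,,2893.263
GGT,Girgentana,Italy,Southern Europe,14.17,37.61,24,0.381,0.381,0.091,-0.00217,,3012.074
MLT,Maltese,Italy,Southern Europe,14.36,37.6,16,0.38,0.391,0.08,0.02903,,2995.381
NIC,Nicastrese,Italy,Southern Europe,16.45,38.93,20,0.407,0.417,0.048,0.02321,,2809.654
ORO,Orobica,Italy,Southern Europe,9.5,46.04,22,0.379,0.375,0.095,-0.01123,,3449.277
RME,Rossa Mediterranea,Italy,Southern Europe,15.57,40.7,30,0.425,0.406,0.059,-0.04794,,2893.263
SAR,Sarda,Italy,Southern Europe,9.22,39.71,27,0.409,0.413,0.054,0.01004,,3432.068
VAL,Valdostana,Italy,Southern Europe,7.38,45.71,24,0.382,0.391,0.078,0.02194,,3607.712
VSS,Valpassiria,Italy,Southern Europe,11.21,46.8,24,0.408,0.413,0.052,0.01119,,3334.609
CRP,Carpathian goat,Romania,Eastern Europe,25.78,46.12,14,0.431,0.428,0.036,-0.00796,,2255.681
BEY,Bermeya,Spain,Southern Europe,-5.26,43.34,23,0.412,0.405,0.067,-0.01901,,4611.009
MAL,Mallorquina,Spain,Southern Europe,3.03,39.55,18,0.378,0.391,0.087,0.03235,,3963.348
MLG,Malagueña,Spain,Southern Europe,-4.42,37.07,40,0.423,0.417,0.053,-0.015,,4650.129
RAS,Blanca de Rasquera,Spain,Southern Europe,0.61,41.0,20,0.39,0.397,0.078,0.01717,,4152.83
ALP_CH,Alpine,Switzerland,Central Europe,7.67,46.95,50,0.41,0.401,0.063,-0.02508,,3603.257
APP,Appenzell,Switzerland,Central Europe,8.23,46.82,29,0.379,0.369,0.104,-0.03135,,3559.048
CHA,Swiss Chamois,Switzerland,Central Europe,8.23,46.82,50,0.413,0.399,0.065,-0.03628,,3559.048
GST,Grisons Striped,Switzerland,Central Europe,8.23,46.82,30,0.405,0.392,0.073,-0.03355,,3559.048
NVE,Nera Verzasca,Switzerland,Central Europe,8.23,46.82,30,0.379,0.375,0.071,-0.00903,,3559.048
PEA,Peacock,Switzerland,Central Europe,8.23,46.82,31,0.408,0.393,0.072,-0.04171,,3559.048
SAA,Saanen,Switzerland,Central Europe,8.23,46.82,30,0.398,0.384,0.087,-0.02897,,3559.048
SGB,Booted goat,Switzerland,Central Europe,8.23,46.82,23,0.395,0.383,0.086,-0.03326,,3559.048
TGR,Tessin grey goat,Switzerland,Central Europe,8.23,46.82,30,0.406,0.399,0.064,-0.01878,,3559.048
TOG,Toggenburg,Switzerland,Central Europe,8.23,46.82,31,0.38,0.372,0.101,-0.02577,,3559.048
VAG,Valais,Switzerland,Central Europe,8.23,46.82,30,0.378,0.373,0.096,-0.01732,,3559.048
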