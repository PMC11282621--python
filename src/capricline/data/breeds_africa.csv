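breed_id,breed_name,country,subregion,lon,lat,n,ho,he,fst_vs_ref,fis,f_roh,distance_km
ALG,Arabia.Makatia.M'Zabite.Kabyle,Algeria,Northern Africa,1.67,28.03,48,0.417,0.432,0.037,0.03302,,4385.501
SAH,Sahel,Burkina Faso,Western Africa,-0.39,14.73,15,0.4,0.397,0.058,-0.00816,,5253.199
BUR,Burundi goat,Burundi,Eastern Africa,29.83,-2.91,50,0.383,0.382,0.065,-0.00482,,4511.944
CAM,Cameroon Goat,Cameroon,Western Africa,14.39,10.11,37,0.39,0.391,0.057,0.0023,,4300.223
WAD_CM,West African Dwarf,Cameroon,Western Africa,10.27,5.9,31,0.371,0.374,0.081,0.00814,,4950.331
PAL,Palmera,Canary Islands,Western Africa,-17.69,28.66,15,0.353,0.348,0.145,-0.01548,,6119.597
BRK,Barki,Egypt,Northern Africa,26.9,29.89,50,0.419,0.42,0.03,0.00109,,1998.527
OSS,Oasis,Egypt,Northern Africa,29.2,26.17,50,0.389,0.411,0.038,0.05391,,1971.097
SID,Saidi,Egypt,Northern Africa,31.58,26.24,50,0.407,0.417,0.031,0.02514,,1766.766
ABR,Abergelle,Ethiopia,Eastern Africa,38.83,13.33,49,0.399,0.396,0.051,-0.00903,,2478.499
GUM,Gumez,Ethiopia,Eastern Africa,36.2,12.97,39,0.404,0.4,0.047,-0.01176,,2620.351
KEF,Keffa,Ethiopia,Eastern Africa,37.0,7.42,44,0.386,0.392,0.056,0.01433,,3161.899
WYG,Woyito Guji,Ethiopia,Eastern Africa,37.48,5.25,39,0.402,0.399,0.047,-0.00926,,3374.868
GAL,Galla,Kenya,Eastern Africa,37.66,2.01,23,0.409,0.402,0.044,-0.01562,,3714.419
SEA,Small East African,Kenya,Eastern Africa,36.97,0.61,30,0.4,0.4,0.044,0.00102,,3883.871
MEN,Malagasy goat (Menabe),Madagascar,Madagascar,45.13,-20.16,19,0.315,0.316,0.145,0.00021,,6029.052
SOF,Malagasy goat (Sofia),Madagascar,Madagascar,47.67,-16.74,22,0.321,0.337,0.143,0.04865,,5645.415
DZD,Dedza,Malawi,Eastern Africa,34.33,-14.37,15,0.351,0.374,0.084,0.06324,,5560.364
GUE,Guera,Mali,Western Africa,-9.19,14.54,16,0.405,0.386,0.078,-0.05274,,6064.181
PEU,Peulh,Mali,Western Africa,-4.2,14.5,22,0.402,0.392,0.062,-0.02748,,5611.567
SDN,Soudanaise,Mali,Western Africa,-6.27,13.45,22,0.397,0.392,0.062,-0.01352,,5862.489
TAR,Targui,Mali,Western Africa,-0.05,16.27,19,0.399,0.396,0.058,-0.00534,,5130.451
MOR,Barcha.Draa.Ghazalia.Morrocan.Noire de l'Atlas.Nord,Morocco,Northern Africa,-7.17,31.09,30,0.405,0.42,0.039,0.03584,,5075.599
LND,Landin,Mozambique,Southern Africa,32.36,-25.5,29,0.333,0.344,0.098,0.0319,,6805.362
RSK,Red Sokoto,Nigeria,Western Africa,8.17,11.89,19,0.387,0.397,0.054,0.02681,,4683.964
SHL,Sahel,Nigeria,Western Africa,8.73,11.25,19,0.402,0.401,0.047,-9e-05,,4680.987
WAD,West African Dwarf,Nigeria,Western Africa,3.74,7.59,19,0.376,0.379,0.082,0.00963,,5361.197
SAFR,South Africa Local breeds (from Limpopo.Freestate.Gauteng.Northwest),South Africa,Southern Africa,26.22,-29.12,26,0.394,0.417,0.038,0.00873,,7364.339
DESE,Desert,Sudan,Eastern Africa,30.37,13.7,24,0.415,0.412,0.038,0.00098,,2857.733
NI,Nilotic,Sudan,Eastern Africa,32.67,13.17,24,0.404,0.41,0.038,-0.01137,,2774.787
TAGG,Taggar,Sudan,Eastern Africa,29.65,12.05,24,0.407,0.404,0.045,0.04142,,3052.918
MAA,Maasai,Tanzania,Eastern Africa,36.65,-11.38,18,0.402,0.398,0.05,-0.00715,,5180.503
PRW,Pare White,Tanzania,Eastern Africa,37.92,-4.25,19,0.393,0.391,0.061,0.01569,,4380.301
SNJ,Sonjo,Tanzania,Eastern Africa,36.32,-2.7,20,0.408,0.392,0.058,-0.00881,,4256.064
TUN,Tunisian,Tunisia,Northern Africa,9.14,35.74,21,0.419,0.42,0.037,-0.00994,,3480.817
KAR,Karamonja,Uganda,Eastern Africa,34.67,2.53,19,0.406,0.403,0.044,-0.00537,,3757.129
MUB,Mubende,Uganda,Eastern Africa,32.29,0.44,18,0.39,0.393,0.059,-0.04145,,4065.861
SEB,Sebei,Uganda,Eastern Africa,34.45,1.4,21,0.405,0.397,0.052,0.00176,,3883.193
MSH,Mashona,Zimbabwe,Southern Africa,31.1,-18.5,22,0.356,0.365,0.078,-0.00709,,6092.687
MTB,Matebele,Zimbabwe,Southern Africa,28.51,-20.55,22,0.41,0.4,0.051,0.00737,,6391.261
BOE,Boer,South Africa,Southern Africa,28.19,-25.75,26,0.397,0.405,,-0.0211,,
SAV,Savanna,South Africa,Southern Africa,23.63,-29.07,27,0.412,0.411,,0.02331,,
KHAR,Kalahari Red,South Africa,Southern Africa,20.15,-25.26,22,0.401,0.406,,-0.02565,,
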