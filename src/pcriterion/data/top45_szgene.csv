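gene,variant_id,location,allele_minor,allele_major,risk_allele,freq_cases,freq_controls,n_cases,n_controls,reported_or,printed_d
MHTFR,rs1801133,1p36.22,T,C,T,0.3532,0.3211,,,1.15,0.032
GRIK3,rs6691840,1p34.3,G,T,G,0.2600,0.2226,,,1.25,0.037
PDE4B,rs910694,1p31.3,C,T,T,0.5780,0.5477,,,1.30,0.030
GSTM1,GSTM1*0,1p13.3,ins-allele,del-allele,del-allele,0.7546,0.7140,,,1.35,0.041
RGS4,rs2661319,1q23.3,A,G,G,0.4920,0.4744,,,1.08,0.0176
IL10,rs1800896,1q32.1,G,A,G,0.3056,0.2657,,,1.42,0.040
PLXNA2,rs841865,1q32.2,A,G,G,0.8434,0.8001,,,1.32,0.043
PLXNA2,rs1327175,1q32.2,G,C,C,0.92840,0.91243,,,1.32,0.016
DISC1,rs3737597,1q42.3,A,G,A,0.03069,0.01735,,,1.80,0.013
DISC1,rs999710,1q42.3,A,G,A,0.3989,0.3819,,,1.07,0.0170
IL1B,rs16944,2q13,T,C,C,0.6289,0.6066,1718,2157,1.11,0.022
ZNF804A,rs1344706,2q32.1,G,T,T,0.6357,0.6032,6487,11478,1.14,0.033
CCKAR,rs1800857,4p15.2,C,T,C,0.1666,0.1559,105,93,1.32,0.008
GABARB2,rs1816072,5q34,C,T,T,0.6404,0.5935,1129,995,1.22,0.047
GABARB2,rs194072,5q34,C,T,T,0.8685,0.8466,1137,991,1.20,0.022
GABARB2,rs6556547,5q34,T,G,G,0.9444,0.9226,774,620,1.43,0.022
DTNBP1,rs3213207,6p23,G,A,A,0.8891,0.8758,8377,8886,1.11,0.013
DTNBP1,rs1474605,6p23,G,A,A,0.8000,0.7858,3710,3588,1.09,0.014
HIST1H2BJ,rs6913660,6p22.1,A,C,C,0.8927,0.8801,10065,34098,1.15,0.013
PRSS16,rs6932590,6p22.1,C,T,T,0.7943,0.8058,7177,28270,1.16,-0.012
PRSS16,rs13219354,6p22.1,C,T,T,0.9088,0.9020,6478,27224,1.20,0.007
PGBD1,rs13211507,6p22.1,C,T,T,0.9518,0.9387,9774,33694,1.23,0.013
RPP21,rs3130375,6p21.33,A,C,C,0.9018,0.8634,2799,3082,1.41,0.038
NOTCH4,rs3131296,6p21.32,A,G,G,0.8912,0.8892,7156,28312,1.20,0.002
NOTCH4,rs2071287,6p21.32,A,G,G,0.6858,0.6463,2511,2556,1.19,0.039
MDGA1,rs11759115,6p21.2,C,T,T,0.8639,0.8379,1874,2582,1.23,0.026
MDGA1,rs12191311,6p21.2,T,C,T,0.3619,0.3555,1879,2605,1.12,0.006
MDGA1,rs7769372,6p21.2,T,C,T,0.2328,0.1885,1915,2576,1.18,0.044
AH1,rs2064430,6q23.3,T,C,T,0.5672,0.5296,2796,13494,1.13,0.038
AH1,rs11154801,6q23.3,A,C,C,0.6633,0.6576,3298,14805,1.09,0.006
C6orf217,rs10223338,6q23.3,T,C,C,0.7158,0.6975,2797,13522,1.12,0.018
C6orf217,rs1475069,6q23.3,C,A,C,0.7205,0.6976,3276,14639,1.14,0.023
C6orf217,rs9321521,6q23.3,A,G,G,0.6755,0.6642,2784,13311,1.12,0.011
RELN,rs7341475,7q22.2,A,G,G,0.8327,0.8110,3315,8042,1.14,0.022
RELN,rs262355,7q22.2,A,T,A,0.3852,0.3563,1128,1848,1.14,0.029
PPP3CC,rs2461491,8p21.3,A,G,A,0.4469,0.4353,6287,6200,1.07,0.015
PPP3CC,rs10108011,8p21.3,G,A,G,0.3657,0.3488,4304,4465,1.09,0.0170
SLC18A1,rs2270641,8p21.3,C,A,C,0.3182,0.2802,759,885,1.63,0.038
NRG1,rs10503929,8p12,C,T,T,0.8342,0.8118,3256,4181,1.14,0.022
GWA_10q26.13,rs17101921,10q26.11,A,G,A,0.06667,0.04318,7447,13039,1.28,0.023
DRD4,rs4646984,11p15.5,S,L,L,0.7750,0.7292,1558,1499,1.27,0.046
DRD4,rs1800955,11p15.5,C,T,C,0.4235,0.4018,2450,2506,1.12,0.022
TPH1,rs1800532,11p15.1,A,C,A,0.4752,0.4299,2416,3623,1.16,0.045
TPH1,rs1799913,11p15.1,A,C,A,0.4546,0.4171,1323,2201,1.14,0.038
GWA_11p14.1,rs1602565,11p14.1,C,T,C,0.1346,0.1152,5475,10845,1.19,0.019
DRD2,rs6277,11q23.1,C,T,C,0.4968,0.4527,3156,3960,1.40,0.044
DRD2,rs6275,11q23.1,T,C,T,0.3106,0.2927,2436,2918,1.15,0.018
DRD2,rs1801028,11q23.1,G,C,G,0.0245,0.0207,4304,5920,1.33,0.004
NRGN,rs12807809,11q24.2,C,T,T,0.8403,0.8190,7213,28490,1.15,0.021
OPCML,rs3016384,11q25,T,C,C,0.5374,0.5141,5491,10900,1.10,0.023
GRIN2B,rs1019385,12p13.1,T,G,G,0.5604,0.4885,687,650,1.33,0.072
DAO,rs4623951,12q24.11,C,T,T,0.7038,0.6788,1509,1521,1.14,0.025
HTR2A,rs6311,13p14.13,A,G,A,0.4441,0.4115,2594,2869,1.21,0.033
DAOA,rs778293,13q33.3,G,A,G,0.3149,0.2770,2899,3218,1.18,0.038
DAOA,rs3916971,13q33.3,T,C,C,0.5622,0.5211,844,922,1.19,0.041
AKT1,rs3803300,14q32.33,A,G,A,0.1068,0.1039,1301,1424,1.36,0.003
GWA_16p13.12,rs7192086,16p13.12,T,A,T,0.2701,0.2456,7179,12623,1.12,0.025
RPGRIP1L,rs9922369,16q12.2,A,G,A,0.0403,0.0336,6494,11449,1.32,0.007
HP,Hp_1/2,16q22.3,1,2,2,0.6208,0.5911,1300,1976,1.14,0.030
SRR,rs408067,17p13.3,G,A,G,0.3166,0.2779,1145,1146,1.22,0.039
TCF4,rs9960767,18q21.2,C,A,C,0.0514,0.0467,9755,33648,1.23,0.005
APOE,e4-allele,19q13.32,E4,E2/3,E4,0.1391,0.1139,1596,3038,1.16,0.025
COMT,rs737865,22q11.21,C,T,T,0.6916,0.6803,7397,10411,1.06,0.011
COMT,rs4818,22q11.21,G,C,G,0.3503,0.3081,177,99,1.05,0.042
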