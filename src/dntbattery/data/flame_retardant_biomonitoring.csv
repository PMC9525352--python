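compound,matrix,region,value,unit,um_reported
BDE-99,breast_milk,Korea,54.0,ng_per_g_lipid,0.0316
BDE-99,breast_milk,China,10.8,ng_per_g_lipid,0.0063
BDE-99,breast_milk,Japan,3.20,ng_per_g_lipid,0.0019
BDE-99,breast_milk,Philippines,0.82,ng_per_g_lipid,0.0005
BDE-99,breast_milk,Vietnam,0.38,ng_per_g_lipid,0.0002
BDE-99,breast_milk,USA,6.40,ng_per_g_lipid,0.0037
BDE-99,breast_milk,France,0.53,ng_per_g_lipid,0.0003
BDE-99,breast_milk,Germany,0.18,ng_per_g_lipid,0.0001
BDE-99,breast_milk,UK,0.80,ng_per_g_lipid,0.0005
BDE-99,breast_milk,Sweden,0.48,ng_per_g_lipid,0.0003
BDE-99,breast_milk,Spain,0.51,ng_per_g_lipid,0.0003
BDE-47,breast_milk,Korea,31.0,ng_per_g_lipid,0.0211
BDE-47,breast_milk,China,27.5,ng_per_g_lipid,0.0187
BDE-47,breast_milk,Japan,4.90,ng_per_g_lipid,0.0033
BDE-47,breast_milk,Philippines,3.60,ng_per_g_lipid,0.0024
BDE-47,breast_milk,Vietnam,0.40,ng_per_g_lipid,0.0003
BDE-47,breast_milk,USA,29.7,ng_per_g_lipid,0.0202
BDE-47,breast_milk,France,1.15,ng_per_g_lipid,0.0008
BDE-47,breast_milk,Germany,0.45,ng_per_g_lipid,0.0003
BDE-47,breast_milk,UK,2.70,ng_per_g_lipid,0.0018
BDE-47,breast_milk,Sweden,2.28,ng_per_g_lipid,0.0015
BDE-47,breast_milk,Spain,0.54,ng_per_g_lipid,0.0004
TBBPA,breast_milk,France,4.1,ng_per_g_lipid,0.0025
BDE-99,cord_blood,Korea,19.0,ng_per_g_lipid,0.0020
BDE-99,cord_blood,China,3.45,ng_per_g_lipid,0.0004
BDE-99,cord_blood,USA,23.3,ng_per_g_lipid,0.0024
BDE-99,cord_blood,France,7.43,ng_per_g_lipid,0.0008
BDE-99,cord_blood,Sweden,0.22,ng_per_g_lipid,0.00002
BDE-99,cord_blood,Spain,4.3,ng_per_g_lipid,0.0004
BDE-47,cord_blood,Korea,36.0,ng_per_g_lipid,0.0044
BDE-47,cord_blood,China,8.49,ng_per_g_lipid,0.0010
BDE-47,cord_blood,Japan,0.12,ng_per_g_lipid,0.00001
BDE-47,cord_blood,USA,4.60,ng_per_g_lipid,0.0006
BDE-47,cord_blood,Sweden,3.4,ng_per_g_lipid,0.0004
BDE-47,cord_blood,Spain,3.3,ng_per_g_lipid,0.0004
TBBPA,cord_blood,France,103,ng_per_g_lipid,0.0111
TPHP,breast_milk,Japan,1.40,ng_per_g_lipid,0.0014
TPHP,breast_milk,Philippines,19.0,ng_per_g_lipid,0.0192
TPHP,breast_milk,Vietnam,4.90,ng_per_g_lipid,0.0050
TPHP,breast_milk,Sweden,8.50,ng_per_g_lipid,0.0086
TPHP,breast_milk,Spain,9.90,ng_per_g_lipid,0.0100
TBOEP,breast_milk,Japan,0.24,ng_per_g_lipid,0.0002
TBOEP,breast_milk,Philippines,22.0,ng_per_g_lipid,0.0182
TBOEP,breast_milk,Sweden,4.70,ng_per_g_lipid,0.0039
TBOEP,breast_milk,Spain,14.8,ng_per_g_lipid,0.0123
TCEP,breast_milk,Japan,0.14,ng_per_g_lipid,0.0002
TCEP,breast_milk,Philippines,42.0,ng_per_g_lipid,0.0554
TCEP,breast_milk,Sweden,4.90,ng_per_g_lipid,0.0065
TCIPP,breast_milk,Sweden,45.0,ng_per_g_lipid,0.0453
TCIPP,breast_milk,Spain,12.5,ng_per_g_lipid,0.0126
EHDPHP,breast_milk,Sweden,6.50,ng_per_g_lipid,0.0059
TCP,breast_milk,Philippines,2.30,ng_per_g_lipid,0.0021
TCP,breast_milk,Vietnam,0.28,ng_per_g_lipid,0.0003
TCP,breast_milk,Sweden,0.80,ng_per_g_lipid,0.0007
TCP,breast_milk,Spain,19.0,ng_per_g_lipid,0.0170
TPHP,breast_milk,USA,0.15,ng_per_mL,0.0005
TBOEP,breast_milk,USA,1.44,ng_per_mL,0.0036
TCEP,breast_milk,USA,0.04,ng_per_mL,0.0001
TCIPP,breast_milk,USA,0.22,ng_per_mL,0.0005
EHDPHP,breast_milk,USA,0.02,ng_per_mL,0.00006
IDDPHP,breast_milk,USA,0.01,ng_per_mL,0.00003
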