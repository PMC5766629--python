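accession,gene,status,avg_shortest_path,betweenness,r_printed
P09417,QDPR,predicted,1.00,0.80000,0.0000
P78334,GABRE,predicted,1.00,0.73889,0.0000
P05451,REG1A,predicted,1.00,0.70370,0.0000
P00918,CA2,predicted,1.00,0.26688,0.0000
P00736,C1R,predicted,1.00,0.14741,0.0000
P11717,IGF2R,predicted,1.65,0.33684,0.0613
P43681,CHRNA4,predicted,1.79,0.51600,0.0746
P42574,CASP3,validated,1.90,0.04377,0.0849
P23141,CES1,predicted,2.13,0.45833,0.1060
P36544,CHRNA7,predicted,2.29,0.09934,0.1217
P35228,NOS2,predicted,2.98,0.05616,0.1865
Q92597,MYC,validated,3.07,0.04787,0.1951
P05089,ARG1,predicted,3.23,0.10864,0.2099
P00966,ASS1,predicted,3.37,0.03375,0.2231
P09211,GSTP1,predicted,3.45,0.10380,0.2251
P04181,OAT,predicted,3.38,0.00546,0.2261
P32929,CTH,predicted,3.40,0.01890,0.2279
P35520,CBS,predicted,3.41,0.00541,0.2310
P08253,MMP2,validated,3.46,0.00064,0.2341
P14210,HGF,predicted,3.47,0.00046,0.2373
P30041,PRDX6,predicted,3.48,0.00605,0.2400
P04075,ALDOA,predicted,3.52,0.00072,0.2403
P11216,PYGB,predicted,3.54,0.00500,0.2407
Q5JWF2,GNAS,predicted,3.54,0.00253,0.2418
P83916,CBX1,predicted,3.55,0.00130,0.2425
P11388,TOP2A,predicted,3.55,0.00104,0.2432
P28482,MAPK1,predicted,3.64,0.02154,0.2486
P03372,ESR1,predicted,3.63,0.00146,0.2503
P10275,AR,validated,3.65,0.00819,0.2505
P35354,PTGS2,predicted,3.67,0.00602,0.2524
P61769,B2M,predicted,3.97,0.11074,0.2751
P13196,ALAS1,predicted,3.92,0.03940,0.2796
P01116,KRAS,predicted,4.15,0.00012,0.2983
P80188,LCN2,predicted,4.16,0.00751,0.2985
P21549,AGXT,predicted,4.17,0.02412,0.3024
O95954,FTCD,predicted,4.20,0.00607,0.3059
P61626,LYZ,predicted,4.25,0.07924,0.3166
P09038,FGF2,predicted,4.35,0.00683,0.3184
P05230,FGF1,predicted,4.38,0.01212,0.3249
Q9Y251,HPSE,validated,4.39,0.00001,0.3266
P11498,PC,predicted,4.45,0.01814,0.3524
P02671,FGA,predicted,4.74,0.04801,0.3790
P05362,ICAM1,validated,5.02,0.05416,0.3813
P16070,CD44,validated,5.04,0.00918,0.3886
Q9UJM8,HAO1,predicted,5.12,0.01655,0.4330
P00915,CA1,predicted,5.59,0.05388,0.4817
P01008,SERPINC1,predicted,6.11,0.01214,0.5011
P05091,ALDH2,predicted,6.31,0.00301,0.8195
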