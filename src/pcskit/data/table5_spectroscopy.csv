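species,block,quantity,value
EA,computed,B0_a,3955.4
EA,computed,B0_b,2009.3
EA,computed,B0_c,1332.6
EAc,computed,B0_a,3891.9
EAc,computed,B0_b,2026.5
EAc,computed,B0_c,1333.0
KA,computed,B0_a,3875.2
KA,computed,B0_b,2026.0
KA,computed,B0_c,1330.4
KI,computed,B0_a,3851.0
KI,computed,B0_b,2024.5
KI,computed,B0_c,1327.6
KIc,computed,B0_a,3863.0
KIc,computed,B0_b,2011.2
KIc,computed,B0_c,1323.3
EA,computed,chi_aa_N1,-2.6818
EA,computed,chi_bb_N1,1.1516
EA,computed,chi_cc_N1,1.5301
EA,computed,chi_aa_N3,2.2536
EA,computed,chi_bb_N3,-3.7073
EA,computed,chi_cc_N3,1.4537
EA,computed,chi_aa_N8,2.1936
EA,computed,chi_bb_N8,1.9946
EA,computed,chi_cc_N8,-4.1882
EAc,computed,chi_aa_N1,-2.8574
EAc,computed,chi_bb_N1,1.0054
EAc,computed,chi_cc_N1,1.8520
EAc,computed,chi_aa_N3,2.2343
EAc,computed,chi_bb_N3,-3.4322
EAc,computed,chi_cc_N3,1.1980
EAc,computed,chi_aa_N8,2.1865
EAc,computed,chi_bb_N8,2.0231
EAc,computed,chi_cc_N8,-4.2096
KA,computed,chi_aa_N1,1.6092
KA,computed,chi_bb_N1,1.4602
KA,computed,chi_cc_N1,-3.0694
KA,computed,chi_aa_N3,2.5229
KA,computed,chi_bb_N3,-3.5884
KA,computed,chi_cc_N3,1.0654
KA,computed,chi_aa_N8,2.1923
KA,computed,chi_bb_N8,1.9159
KA,computed,chi_cc_N8,-4.1082
KI,computed,chi_aa_N1,1.8615
KI,computed,chi_bb_N1,2.0432
KI,computed,chi_cc_N1,-3.9047
KI,computed,chi_aa_N3,2.1311
KI,computed,chi_bb_N3,1.6010
KI,computed,chi_cc_N3,-3.7321
KI,computed,chi_aa_N8,1.8367
KI,computed,chi_bb_N8,-3.1411
KI,computed,chi_cc_N8,1.3044
KIc,computed,chi_aa_N1,2.1259
KIc,computed,chi_bb_N1,1.7903
KIc,computed,chi_cc_N1,-3.9162
KIc,computed,chi_aa_N3,1.8548
KIc,computed,chi_bb_N3,2.0767
KIc,computed,chi_cc_N3,-3.9315
KIc,computed,chi_aa_N8,-2.1965
KIc,computed,chi_bb_N8,0.9632
KIc,computed,chi_cc_N8,1.2333
EA,computed,mu_a,-2.9632
EA,computed,mu_b,1.3316
EA,computed,mu_c,-0.6243
EAc,computed,mu_a,-4.4160
EAc,computed,mu_b,-0.9458
EAc,computed,mu_c,-0.6612
KA,computed,mu_a,-4.4651
KA,computed,mu_b,4.6748
KA,computed,mu_c,-0.4753
KI,computed,mu_a,-0.6290
KI,computed,mu_b,4.6635
KI,computed,mu_c,0.0000
KIc,computed,mu_a,0.6886
KIc,computed,mu_b,2.3435
KIc,computed,mu_c,0.0000
EA,computed,dG0,0
EAc,computed,dG0,247
KA,computed,dG0,161
KI,computed,dG0,579
KIc,computed,dG0,1136
EA,experimental,B0_a,3951.85325
EA,experimental,B0_b,2008.95802
EA,experimental,B0_c,1332.47228
EAc,experimental,B0_a,3889.46510
EAc,experimental,B0_b,2026.31804
EAc,experimental,B0_c,1332.86951
KA,experimental,B0_a,3871.54618
KA,experimental,B0_b,2024.97804
KA,experimental,B0_c,1330.33627
KI,experimental,B0_a,3848.18174
KI,experimental,B0_b,2026.31068
KI,experimental,B0_c,1327.99167
KIc,experimental,B0_a,3861.2966
KIc,experimental,B0_b,2011.41032
KIc,experimental,B0_c,1323.19999
EA,experimental,chi_aa_N1,-2.6373
EA,experimental,chi_bb_N1,1.1672
EA,experimental,chi_cc_N1,1.4701
EA,experimental,chi_aa_N3,2.2619
EA,experimental,chi_bb_N3,-3.6570
EA,experimental,chi_cc_N3,1.3951
EA,experimental,chi_aa_N8,2.2167
EA,experimental,chi_bb_N8,1.9511
EA,experimental,chi_cc_N8,-4.1678
EAc,experimental,chi_aa_N1,-2.8007
EAc,experimental,chi_bb_N1,1.0340
EAc,experimental,chi_cc_N1,1.7667
EAc,experimental,chi_aa_N3,2.2371
EAc,experimental,chi_bb_N3,-3.3890
EAc,experimental,chi_cc_N3,1.1519
EAc,experimental,chi_aa_N8,2.2237
EAc,experimental,chi_bb_N8,1.9832
EAc,experimental,chi_cc_N8,-4.2069
KA,experimental,chi_aa_N1,1.6211
KA,experimental,chi_bb_N1,1.4772
KA,experimental,chi_cc_N1,-3.0983
KA,experimental,chi_aa_N3,2.5217
KA,experimental,chi_bb_N3,-3.5140
KA,experimental,chi_cc_N3,0.9923
KA,experimental,chi_aa_N8,2.1802
KA,experimental,chi_bb_N8,1.8429
KA,experimental,chi_cc_N8,-4.0231
KI,experimental,chi_aa_N1,1.8518
KI,experimental,chi_bb_N1,2.0545
KI,experimental,chi_cc_N1,-3.9063
KI,experimental,chi_aa_N3,2.1383
KI,experimental,chi_bb_N3,1.6064
KI,experimental,chi_cc_N3,-3.7448
KI,experimental,chi_aa_N8,1.8033
KI,experimental,chi_bb_N8,-3.1572
KI,experimental,chi_cc_N8,1.3539
KIc,experimental,chi_aa_N1,1.898
KIc,experimental,chi_bb_N1,2.104
KIc,experimental,chi_cc_N1,-4.002
KIc,experimental,chi_aa_N3,2.105
KIc,experimental,chi_bb_N3,1.764
KIc,experimental,chi_cc_N3,-3.870
KIc,experimental,chi_aa_N8,-2.091
KIc,experimental,chi_bb_N8,0.940
KIc,experimental,chi_cc_N8,1.151
EA,experimental,dG0,0
EAc,experimental,dG0,165
KA,experimental,dG0,40
KI,experimental,dG0,290
KIc,experimental,dG0,
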