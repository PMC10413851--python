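species,mode_index,label,b3_h,b3_anh,rdsd_h,hybrid_printed,intensity,exp_freq,exp_intensity
KI,1,nu(N1H),3640,3467,3668,3495,114,,
KI,2,nu(N3H),3597,3423,3618,3444,65,,
KI,3,nu(N8H),3493,3314,3523,3344,11,,
KI,4,nu(C5H),3245,3108,3248,3111,1,,
KI,5,nu(C6H),3224,3084,3222,3082,2,,
KI,6,nu(C2O),1803,1765,1803,1765,814,,
KI,7,nu(C5C6),1721,1682,1725,1686,421,,
KI,8,beta(N8H),1663,1620,1659,1616,23,,
KI,9,nu(N3C4),1509,1475,1514,1480,95,,
KI,10,nu(N3C4),1445,1411,1453,1419,78,,
KI,11,beta(N1H),1424,1384,1417,1377,11,,
KI,12,nu(C4N),1407,1372,1409,1374,21,,
KI,13,nu(C2N3),1311,1270,1323,1282,19,,
KI,14,beta(C6H),1227,1210,1219,1202,92,,
KI,15,beta(C5H),1152,1119,1155,1122,140,,
KI,16,beta(N8H),1097,1078,1097,1078,1,,
KI,17,beta(R1),993,976,998,981,7,,
KI,18,beta(C6H),970,949,974,953,9,,
KI,19,nu(N1C2),770,750,772,752,5,,
KI,20,beta(R2),567,560,566,559,7,,
KI,21,beta(R3),534,528,536,530,3,,
KI,22,beta(CO),518,513,515,510,32,,
KI,23,beta(C4N),376,376,376,376,10,,
KI,24,gamma(CO),953,935,966,948,1,,
KI,25,gamma(C4N),828,808,841,821,82,,
KI,26,gamma(CO),769,757,779,767,4,,
KI,27,gamma(C5H),736,741,758,763,36,,
KI,28,gamma(N1H),699,689,708,698,10,,
KI,29,tau(NH),657,646,659,648,95,,
KI,30,tau(R2),527,529,518,520,35,,
KI,31,tau(NH),386,383,383,380,21,,
KI,32,tau(R3),157,159,152,154,2,,
KI,33,tau(R2),137,139,130,132,0,,
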