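species,mode_index,label,b3_h,b3_anh,rdsd_h,hybrid_printed,intensity,exp_freq,exp_intensity
KA,1,nu(asNH2),3715,3577,3749,3611,50,3564,122
KA,2,nu(N1H),3612,3441,3640,3469,82,3472,123
KA,3,nu(sNH2),3590,3459,3611,3480,88,3441,192
KA,4,nu(C5H),3236,3099,3243,3106,1,,
KA,5,nu(C6H),3215,3104,3216,3105,2,,
KA,6,nu(C2O),1776,1746,1774,1744,751,1719,782
KA,7,nu(C5C6),1696,1654,1704,1662,470,1656,384
KA,8,beta(scNH2),1657,1609,1643,1595,130,1598,312
KA,9,nu(N3C4),1575,1535,1586,1546,162,1539,113
KA,10,nu(N3C4),1513,1488,1516,1491,154,1475,242
KA,11,beta(N1H),1453,1419,1453,1419,73,1423,30
KA,12,nu(C4N),1364,1345,1365,1346,59,1337,66
KA,13,nu(C2N3),1265,1237,1272,1244,22,1244,28
KA,14,beta(C6H),1228,1205,1221,1198,55,1196,49
KA,15,beta(C5H),1134,1118,1130,1114,1,,
KA,16,beta(roNH2),1099,1043,1108,1052,44,1090,56
KA,17,beta(R1),990,970,992,972,1,,
KA,18,gamma(C6H),959,942,975,958,1,,
KA,19,nu(N1C2),929,901,937,909,3,,
KA,20,gamma(C2O),773,766,792,775,40,781,32
KA,21,gamma(C2O),768,762,779,773,7,,
KA,22,gamma(C4N),763,758,773,768,6,747,34
KA,23,gamma(C5H),725,715,734,724,31,716,39
KA,24,gamma(N1H),628,621,630,623,59,614,85
KA,25,beta(R2),578,572,576,570,2,575,76
KA,26,beta(R3),547,545,546,544,5,568,58
KA,27,tau(toNH2),532,541,536,545,3,535,24
KA,28,beta(C2O),522,566,529,573,14,,
KA,29,tau(R2),397,398,401,402,19,400,23
KA,30,beta(C4N),359,353,359,353,2,,
KA,31,tau(invNH2),246,-710,266,266,233,235,244
KA,32,tau(R3),202,189,204,191,6,,
KA,33,tau(R2),135,136,133,134,2,,
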