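species,mode_index,label,b3_h,b3_anh,rdsd_h,hybrid_printed,intensity,exp_freq,exp_intensity
EA,1,nu(OH),3715,3525,3793,3603,99,3592,168
EA,2,nu(asNH2),3709,3560,3739,3590,46,3564,98
EA,3,nu(sNH2),3588,3450,3608,3470,71,3446,154
EA,4,nu(C5H),3217,3090,3223,3096,5,,
EA,5,nu(C6H),3184,3062,3183,3063,14,,
EA,6,nu(C5C6),1674,1625,1671,1623,565,1622,645
EA,7,beta(scNH2),1651,1607,1643,1599,12,1589,64
EA,8,nu(N3C4),1616,1570,1625,1579,256,1570,52
EA,9,beta(C5H),1531,1494,1534,1497,36,1496,73
EA,10,nu(CO),1476,1440,1478,1442,408,1427,285
EA,11,nu(C5C6),1408,1383,1410,1385,46,,
EA,12,beta(C6H),1357,1317,1353,1313,173,1320,72
EA,13,beta(OH),1311,1279,1291,1259,27,,
EA,14,nu(N1C2),1250,1216,1250,1216,34,1196,124
EA,15,beta(C5H),1137,1115,1133,1111,39,1110,29
EA,16,beta(roNH2),1106,1067,1106,1067,43,1083,60
EA,17,gamma(C6H),1008,989,1008,989,9,,
EA,18,beta(R1),995,973,1006,984,1,980,30
EA,19,nu(C4C5),992,973,995,976,16,955,3
EA,20,gamma(CO),816,810,827,821,51,807,69
EA,21,gamma(C5H),796,784,804,792,1,,
EA,22,beta(R1),792,778,796,782,7,781,30
EA,23,gamma(CO),716,716,728,728,4,710,8
EA,24,beta(R3),601,593,601,593,1,,
EA,25,tau(OH),563,550,562,551,28,557,21
EA,26,beta(R2),571,522,562,523,71,520,221
EA,27,tau(toNH2),511,489,511,489,15,507,67
EA,28,tau(toNH2),491,460,493,462,12,498,42
EA,29,tau(R3),450,444,451,445,16,443,13
EA,30,beta(CN8),343,329,342,328,45,343,11
EA,31,tau(invNH2),321,-216,348,348,219,235,244
EA,32,tau(invNH2),220,216,220,216,12,,
EA,33,tau(R2),186,185,187,186,1,,
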