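species,level,Ba_eq,Bb_eq,Bc_eq,dBa_vib,dBb_vib,dBc_vib
EA,B3,3935.4,1996.1,1324.9,27.6,11.0,8.6
EA,rDSD,3963.7,2011.1,1334.9,29.3,11.6,8.9
EAc,B3,3870.1,2014.3,1325.4,23.9,12.6,8.8
EAc,rDSD,3898.4,2029.6,1335.5,25.4,13.1,9.0
KA,B3,3850.9,1992.1,1312.9,27.4,9.4,7.9
KA,rDSD,3884.8,2025.9,1331.9,29.1,9.9,8.1
KI,B3,3830.0,2010.4,1318.4,29.4,11.0,7.7
KI,rDSD,3861.7,2026.9,1329.2,30.8,11.7,8.0
KIc,B3,3850.9,1992.1,1312.9,28.4,11.4,7.7
KIc,rDSD,3875.2,2012.3,1324.5,29.7,12.0,8.0
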