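species,axis,method,value_MHz
uracil,a,SE,3913.3
uracil,b,SE,2035.2
uracil,c,SE,1338.9
uracil,a,rDSD/j3,3895.2
uracil,b,rDSD/j3,2022.2
uracil,c,rDSD/j3,1331.2
uracil,a,rDSD,3901.8
uracil,b,rDSD,2026.8
uracil,c,rDSD,1333.9
uracil,a,PCS,3913.3
uracil,b,PCS,2033.3
uracil,c,PCS,1338.1
uracil,a,B3LYP,3875.9
uracil,b,B3LYP,2010.9
uracil,c,B3LYP,1324.0
KA,a,SE,3899.0
KA,b,SE,2034.4
KA,c,SE,1338.2
KA,a,rDSD/j3,3884.8
KA,b,rDSD/j3,2025.9
KA,c,rDSD/j3,1331.9
KA,a,rDSD,3890.5
KA,b,rDSD,2029.7
KA,c,rDSD,1334.3
KA,a,PCS,3904.3
KA,b,PCS,2035.9
KA,c,PCS,1338.5
KA,a,B3LYP,3850.9
KA,b,B3LYP,1992.1
KA,c,B3LYP,1312.9
EA,a,SE,3979.5
EA,b,SE,2020.0
EA,c,SE,1341.1
EA,a,rDSD/j3,3963.8
EA,b,rDSD/j3,2011.3
EA,c,rDSD/j3,1334.9
EA,a,rDSD,3970.4
EA,b,rDSD,2014.6
EA,c,rDSD,1337.1
EA,a,PCS,3984.7
EA,b,PCS,2020.9
EA,c,PCS,1341.5
EA,a,B3LYP,3935.4
EA,b,B3LYP,1996.1
EA,c,B3LYP,1324.9
EAc,a,SE,3920.1
EAc,b,SE,2040.5
EAc,c,SE,1342.7
EAc,a,rDSD/j3,3898.4
EAc,b,rDSD/j3,2029.6
EAc,c,rDSD/j3,1335.5
EAc,a,rDSD,3904.1
EAc,b,rDSD,2033.3
EAc,c,rDSD,1337.7
EAc,a,PCS,3917.3
EAc,b,PCS,2039.6
EAc,c,PCS,1342.0
EAc,a,B3LYP,3870.1
EAc,b,B3LYP,2014.3
EAc,c,B3LYP,1325.4
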