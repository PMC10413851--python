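species,axis,method,value_MHz
KI,a,SE,3877.6
KI,b,SE,2037.3
KI,c,SE,1335.7
KI,a,rDSD,3867.7
KI,b,rDSD,2030.7
KI,c,rDSD,1331.6
KI,a,rDSD+CV,3881.8
KI,b,rDSD+CV,2036.2
KI,c,rDSD+CV,1335.6
KI,a,CC-F12/j3,3863.0
KI,b,CC-F12/j3,2030.2
KI,c,CC-F12/j3,1330.8
KI,a,CC-F12/j3+CV,3877.7
KI,b,CC-F12/j3+CV,2035.2
KI,c,CC-F12/j3+CV,1334.7
KIc,a,SE,3889.7
KIc,b,SE,2022.8
KIc,c,SE,1330.9
KIc,a,rDSD,3880.3
KIc,b,rDSD,2016.3
KIc,c,rDSD,1326.8
KIc,a,rDSD+CV,3892.7
KIc,b,rDSD+CV,2023.2
KIc,c,rDSD+CV,1331.3
KIc,a,CC-F12/j3,3875.2
KIc,b,CC-F12/j3,2016.0
KIc,c,CC-F12/j3,1326.1
KIc,a,CC-F12/j3+CV,3887.7
KIc,b,CC-F12/j3+CV,2023.0
KIc,c,CC-F12/j3+CV,1330.6
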