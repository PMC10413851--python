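species,B3,rDSD,MP2_j3,CC_j3,dCBS_conv,CC_F12,dCBS_F12,dCV,total,dZPE
EA,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
EAc,277.7,257.9,249.3,239.6,6.6,246.1,1.2,2.9,250.2,-5.2
KA,-601.3,-104.8,588.9,402.5,-102.7,320.0,-8.5,-23.9,287.6,-45.0
KI,82.4,185.7,1104.1,601.4,-68.4,565.4,-7.2,-16.0,542.2,101.5
KIc,741.7,800.5,1712.9,1180.3,-50.1,1160.0,-6.2,-5.7,1148.1,57.3
KA1,1809.0,2447.3,3157.9,2927.7,5.3,2898.2,0.6,0.6,2899.4,
EI1,4143.3,4271.9,4792.6,4298.5,-2.5,4330.5,-0.3,21.4,4351.6,
EI,6480.9,5880.1,6413.3,5824.6,-2.3,5867.8,-0.2,13.8,5881.4,
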