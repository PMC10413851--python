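species,method,stat,value
uracil,rDSD/j3,MUE,10.4
uracil,rDSD/j3,MAX,18.1
uracil,rDSD/j3,MUE%,0.63
uracil,rDSD/j3,MAX%,0.56
uracil,rDSD,MUE,8.3
uracil,rDSD,MAX,11.5
uracil,rDSD,MUE%,0.36
uracil,rDSD,MAX%,0.41
uracil,PCS,MUE,0.9
uracil,PCS,MAX,1.9
uracil,PCS,MUE%,0.05
uracil,PCS,MAX%,0.09
uracil,B3LYP,MUE,25.5
uracil,B3LYP,MAX,37.4
uracil,B3LYP,MUE%,1.09
uracil,B3LYP,MAX%,1.19
KA,rDSD/j3,MUE,9.7
KA,rDSD/j3,MAX,14.2
KA,rDSD/j3,MUE%,0.42
KA,rDSD/j3,MAX%,0.47
KA,rDSD,MUE,5.7
KA,rDSD,MAX,8.5
KA,rDSD,MUE%,0.25
KA,rDSD,MAX%,0.29
KA,PCS,MUE,2.4
KA,PCS,MAX,5.3
KA,PCS,MUE%,0.08
KA,PCS,MAX%,0.14
KA,B3LYP,MUE,29.9
KA,B3LYP,MAX,48.9
KA,B3LYP,MUE%,1.27
KA,B3LYP,MAX%,1.23
EA,rDSD/j3,MUE,10.2
EA,rDSD/j3,MAX,15.7
EA,rDSD/j3,MUE%,0.43
EA,rDSD/j3,MAX%,0.46
EA,rDSD,MUE,6.3
EA,rDSD,MAX,9.5
EA,rDSD,MUE%,0.27
EA,rDSD,MAX%,0.30
EA,PCS,MUE,2.2
EA,PCS,MAX,5.2
EA,PCS,MUE%,0.07
EA,PCS,MAX%,0.13
EA,B3LYP,MUE,28.1
EA,B3LYP,MAX,44.1
EA,B3LYP,MUE%,1.17
EA,B3LYP,MAX%,1.21
EAc,rDSD/j3,MUE,13.3
EAc,rDSD/j3,MAX,21.7
EAc,rDSD/j3,MUE%,0.54
EAc,rDSD/j3,MAX%,0.55
EAc,rDSD,MUE,3.1
EAc,rDSD,MAX,7.2
EAc,rDSD,MUE%,0.38
EAc,rDSD,MAX%,0.41
EAc,PCS,MUE,1.5
EAc,PCS,MAX,2.8
EAc,PCS,MUE%,0.05
EAc,PCS,MAX%,0.07
EAc,B3LYP,MUE,31.2
EAc,B3LYP,MAX,50.0
EAc,B3LYP,MUE%,1.28
EAc,B3LYP,MAX%,1.29
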