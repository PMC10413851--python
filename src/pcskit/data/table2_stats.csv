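species,method,stat,value
KI,rDSD,MUE,6.9
KI,rDSD,MAX,9.9
KI,rDSD,MUE%,0.30
KI,rDSD,MAX%,0.32
KI,rDSD+CV,MUE,1.8
KI,rDSD+CV,MAX,4.2
KI,rDSD+CV,MUE%,0.06
KI,rDSD+CV,MAX%,0.11
KI,CC-F12/j3,MUE,8.9
KI,CC-F12/j3,MAX,14.6
KI,CC-F12/j3,MUE%,0.37
KI,CC-F12/j3,MAX%,0.38
KI,CC-F12/j3+CV,MUE,1.1
KI,CC-F12/j3+CV,MAX,2.1
KI,CC-F12/j3+CV,MUE%,0.07
KI,CC-F12/j3+CV,MAX%,0.10
KIc,rDSD,MUE,6.7
KIc,rDSD,MAX,9.4
KIc,rDSD,MUE%,0.29
KIc,rDSD,MAX%,0.32
KIc,rDSD+CV,MUE,1.3
KIc,rDSD+CV,MAX,3.0
KIc,rDSD+CV,MUE%,0.04
KIc,rDSD+CV,MAX%,0.07
KIc,CC-F12/j3,MUE,8.7
KIc,CC-F12/j3,MAX,14.5
KIc,CC-F12/j3,MUE%,0.36
KIc,CC-F12/j3,MAX%,0.37
KIc,CC-F12/j3+CV,MUE,0.8
KIc,CC-F12/j3+CV,MAX,2.0
KIc,CC-F12/j3+CV,MUE%,0.03
KIc,CC-F12/j3+CV,MAX%,0.05
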