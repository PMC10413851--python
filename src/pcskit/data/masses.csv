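element,isotope,mass_amu,principal
H,1,1.00782503190,1
H,2,2.01410177784,0
C,12,12.0,1
C,13,13.00335483534,0
N,14,14.00307400425,1
N,15,15.00010889827,0
O,16,15.99491461926,1
O,17,16.99913175595,0
O,18,17.99915961214,0
S,32,31.97207117354,1
S,34,33.96786701,0
F,19,18.99840316207,1
P,31,30.97376199768,1
Cl,35,34.96885269,1
Cl,37,36.96590258,0
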