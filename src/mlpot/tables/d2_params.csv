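# DFT-D2 dispersion parameters per element (Grimme 2006 semiempirical GGA-type DFT-D)
# c6: J nm^6 mol^-1, r_vdw: Angstrom
z,symbol,c6,r_vdw
1,H,0.14,1.001
2,He,0.08,1.012
3,Li,1.61,0.825
4,Be,1.61,1.408
5,B,3.13,1.485
6,C,1.75,1.452
7,N,1.23,1.397
8,O,0.70,1.342
9,F,0.75,1.287
10,Ne,0.63,1.243
11,Na,5.71,1.144
12,Mg,5.71,1.364
13,Al,10.79,1.639
14,Si,9.23,1.716
15,P,7.84,1.705
16,S,5.57,1.683
17,Cl,5.07,1.639
18,Ar,4.61,1.595
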