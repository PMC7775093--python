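# Standard atomic weights (CIAAW 2021 abridged) and atomic numbers.
# One self-consistent table used everywhere in the package, including the
# (Z/A) of water that normalizes relative electron density.
symbol,Z,A
H,1,1.008
He,2,4.0026
Li,3,6.94
Be,4,9.0122
B,5,10.81
C,6,12.011
N,7,14.007
O,8,15.999
F,9,18.998
Ne,10,20.180
Na,11,22.990
Mg,12,24.305
Al,13,26.982
Si,14,28.085
P,15,30.974
S,16,32.06
Cl,17,35.45
Ar,18,39.95
K,19,39.098
Ca,20,40.078
Ti,22,47.867
Cr,24,51.996
Mn,25,54.938
Fe,26,55.845
Ni,28,58.693
Cu,29,63.546
Zn,30,65.38
I,53,126.90
Ba,56,137.33
W,74,183.84
Pb,82,207.2
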