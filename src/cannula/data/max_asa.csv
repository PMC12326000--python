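aa,max_asa_nm2
A,1.290
R,2.740
N,1.950
D,1.930
C,1.670
E,2.230
Q,2.250
G,1.040
H,2.240
I,1.970
L,2.010
K,2.360
M,2.240
F,2.400
P,1.590
S,1.550
T,1.720
W,2.850
Y,2.630
V,1.740
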