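residue,weight
A,1.00
L,0.79
R,0.79
M,0.76
K,0.74
Q,0.61
E,0.60
I,0.59
W,0.51
S,0.50
Y,0.47
F,0.46
H,0.39
V,0.39
N,0.35
T,0.34
C,0.32
D,0.31
G,0.02
P,0.00
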