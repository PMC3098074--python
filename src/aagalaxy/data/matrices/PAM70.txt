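# PAM70 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 70 substitution matrix, scale = ln(2)/2 = 0.346574
# Expected score = -2.77, Entropy = 1.60 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 5 -4 -1 -1 -6 0 -4 -2 -4 -4 -3 -2 0 -2 -4 1 1 -1 -9 -5
C -4 9 -9 -9 -8 -6 -5 -4 -9 -10 -9 -7 -5 -9 -5 -1 -5 -4 -11 -2
D -1 -9 6 3 -10 -1 -1 -5 -2 -8 -7 3 -4 0 -6 -1 -2 -5 -10 -7
E -1 -9 3 6 -9 -2 -2 -4 -2 -6 -4 0 -3 2 -5 -2 -3 -4 -11 -6
F -6 -8 -10 -9 8 -7 -4 0 -9 -1 -2 -6 -7 -9 -7 -4 -6 -5 -2 4
G 0 -6 -1 -2 -7 6 -6 -6 -5 -7 -6 -1 -3 -4 -6 0 -3 -3 -10 -9
H -4 -5 -1 -2 -4 -6 8 -6 -3 -4 -6 1 -2 2 0 -3 -4 -4 -5 -1
I -2 -4 -5 -4 0 -6 -6 7 -4 1 1 -3 -5 -5 -3 -4 -1 3 -9 -4
K -4 -9 -2 -2 -9 -5 -3 -4 6 -5 0 0 -4 -1 2 -2 -1 -6 -7 -7
L -4 -10 -8 -6 -1 -7 -4 1 -5 6 2 -5 -5 -3 -6 -6 -4 0 -4 -4
M -3 -9 -7 -4 -2 -6 -6 1 0 2 10 -5 -5 -2 -2 -3 -2 0 -8 -7
N -2 -7 3 0 -6 -1 1 -3 0 -5 -5 6 -3 -1 -3 1 0 -5 -6 -3
P 0 -5 -4 -3 -7 -3 -2 -5 -4 -5 -5 -3 7 -1 -2 0 -2 -3 -9 -9
Q -2 -9 0 2 -9 -4 2 -5 -1 -3 -2 -1 -1 7 0 -3 -3 -4 -8 -8
R -4 -5 -6 -5 -7 -6 0 -3 2 -6 -2 -3 -2 0 8 -1 -4 -5 0 -7
S 1 -1 -1 -2 -4 0 -3 -4 -2 -6 -3 1 0 -3 -1 5 2 -3 -3 -5
T 1 -5 -2 -3 -6 -3 -4 -1 -1 -4 -2 0 -2 -3 -4 2 6 -1 -8 -4
V -1 -4 -5 -4 -5 -3 -4 3 -6 0 0 -5 -3 -4 -5 -3 -1 6 -10 -5
W -9 -11 -10 -11 -2 -10 -5 -9 -7 -4 -8 -6 -9 -8 0 -3 -8 -10 13 -3
Y -5 -2 -7 -6 4 -9 -1 -4 -7 -4 -7 -3 -9 -8 -7 -5 -4 -5 -3 9
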