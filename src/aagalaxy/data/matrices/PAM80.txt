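# PAM80 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 80 substitution matrix, scale = ln(2)/2 = 0.346574
# Expected score = -2.55, Entropy = 1.44 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 4 -4 -1 -1 -5 0 -4 -2 -4 -4 -3 -1 0 -2 -4 1 1 0 -8 -5
C -4 9 -9 -9 -8 -6 -5 -4 -9 -9 -8 -6 -5 -9 -5 -1 -4 -3 -10 -2
D -1 -9 6 4 -9 -1 -1 -4 -2 -7 -6 3 -4 0 -5 -1 -2 -5 -10 -7
E -1 -9 4 6 -9 -2 -2 -3 -2 -6 -4 0 -3 2 -4 -2 -3 -4 -11 -6
F -5 -8 -9 -9 8 -6 -3 0 -9 0 -2 -5 -7 -8 -6 -4 -5 -4 -2 4
G 0 -6 -1 -2 -6 6 -5 -6 -4 -7 -5 -1 -3 -4 -6 0 -2 -3 -10 -8
H -4 -5 -1 -2 -3 -5 8 -5 -3 -4 -5 2 -2 2 0 -3 -4 -4 -4 -1
I -2 -4 -4 -3 0 -6 -5 7 -4 1 1 -3 -5 -4 -3 -4 -1 3 -8 -3
K -4 -9 -2 -2 -9 -4 -3 -4 6 -5 0 0 -4 -1 2 -2 -1 -5 -7 -6
L -4 -9 -7 -6 0 -7 -4 1 -5 6 2 -5 -4 -3 -5 -5 -4 0 -3 -4
M -3 -8 -6 -4 -2 -5 -5 1 0 2 9 -4 -5 -2 -2 -3 -2 1 -7 -6
N -1 -6 3 0 -5 -1 2 -3 0 -5 -4 5 -3 -1 -2 1 0 -4 -5 -3
P 0 -5 -4 -3 -7 -3 -2 -5 -4 -4 -5 -3 7 -1 -2 0 -2 -3 -9 -8
Q -2 -9 0 2 -8 -4 2 -4 -1 -3 -2 -1 -1 7 0 -3 -3 -4 -8 -7
R -4 -5 -5 -4 -6 -6 0 -3 2 -5 -2 -2 -2 0 7 -1 -3 -5 0 -7
S 1 -1 -1 -2 -4 0 -3 -4 -2 -5 -3 1 0 -3 -1 4 2 -3 -3 -4
T 1 -4 -2 -3 -5 -2 -4 -1 -1 -4 -2 0 -2 -3 -3 2 5 -1 -8 -4
V 0 -3 -5 -4 -4 -3 -4 3 -5 0 1 -4 -3 -4 -5 -3 -1 6 -10 -5
W -8 -10 -10 -11 -2 -10 -4 -8 -7 -3 -7 -5 -9 -8 0 -3 -8 -10 13 -2
Y -5 -2 -7 -6 4 -8 -1 -3 -6 -4 -6 -3 -8 -7 -7 -4 -4 -5 -2 9
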