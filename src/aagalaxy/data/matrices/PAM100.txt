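# PAM100 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 100 substitution matrix, scale = ln(2)/2 = 0.346574
# Expected score = -1.99, Entropy = 1.18 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 4 -3 -1 0 -5 1 -3 -2 -3 -3 -2 -1 1 -2 -3 1 1 0 -7 -4
C -3 9 -7 -8 -7 -5 -4 -3 -8 -8 -7 -5 -4 -8 -5 -1 -4 -3 -9 -1
D -1 -7 5 4 -8 -1 -1 -4 -1 -6 -5 3 -3 0 -4 -1 -2 -4 -9 -6
E 0 -8 4 5 -8 -1 -1 -3 -1 -5 -4 1 -2 2 -3 -1 -2 -3 -9 -5
F -5 -7 -8 -8 8 -6 -3 0 -7 0 -1 -5 -6 -7 -6 -4 -5 -3 -1 4
G 1 -5 -1 -1 -6 5 -4 -5 -3 -6 -4 -1 -2 -3 -5 0 -2 -3 -9 -7
H -3 -4 -1 -1 -3 -4 7 -4 -2 -3 -4 2 -1 3 1 -2 -3 -3 -4 -1
I -2 -3 -4 -3 0 -5 -4 6 -3 1 1 -3 -4 -4 -3 -3 0 3 -7 -3
K -3 -8 -1 -1 -7 -3 -2 -3 5 -4 0 1 -3 0 2 -1 -1 -4 -6 -6
L -3 -8 -6 -5 0 -6 -3 1 -4 6 3 -4 -4 -2 -5 -4 -3 0 -3 -3
M -2 -7 -5 -4 -1 -4 -4 1 0 3 9 -4 -4 -2 -1 -3 -1 1 -6 -5
N -1 -5 3 1 -5 -1 2 -3 1 -4 -4 5 -2 -1 -2 1 0 -3 -5 -2
P 1 -4 -3 -2 -6 -2 -1 -4 -3 -4 -4 -2 7 -1 -1 0 -1 -3 -7 -7
Q -2 -8 0 2 -7 -3 3 -4 0 -2 -2 -1 -1 6 1 -2 -2 -3 -7 -6
R -3 -5 -4 -3 -6 -5 1 -3 2 -5 -1 -2 -1 1 7 -1 -3 -4 1 -6
S 1 -1 -1 -1 -4 0 -2 -3 -1 -4 -3 1 0 -2 -1 4 2 -2 -3 -4
T 1 -4 -2 -2 -5 -2 -3 0 -1 -3 -1 0 -1 -2 -3 2 5 0 -7 -4
V 0 -3 -4 -3 -3 -3 -3 3 -4 0 1 -3 -3 -3 -4 -2 0 5 -9 -4
W -7 -9 -9 -9 -1 -9 -4 -7 -6 -3 -6 -5 -7 -7 1 -3 -7 -9 12 -2
Y -4 -1 -6 -5 4 -7 -1 -3 -6 -3 -5 -2 -7 -6 -6 -4 -4 -4 -2 9
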