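# PAM270 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 270 substitution matrix, scale = ln(2)/4 = 0.173287
# Expected score = -0.969, Entropy = 0.309 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 2 -2 0 0 -4 2 -2 -1 -1 -2 -1 0 1 0 -2 1 1 0 -7 -4
C -2 16 -6 -6 -5 -4 -4 -3 -7 -7 -6 -4 -3 -7 -5 0 -3 -2 -10 1
D 0 -6 5 4 -7 1 1 -3 0 -5 -3 2 -1 2 -1 0 0 -3 -8 -5
E 0 -6 4 5 -7 0 1 -2 0 -4 -3 2 -1 3 -1 0 0 -2 -9 -5
F -4 -5 -7 -7 12 -6 -2 1 -6 2 0 -4 -6 -6 -5 -4 -4 -1 1 9
G 2 -4 1 0 -6 6 -2 -3 -2 -5 -3 1 0 -1 -3 1 0 -2 -9 -6
H -2 -4 1 1 -2 -2 8 -3 0 -3 -3 2 0 4 2 -1 -1 -3 -3 0
I -1 -3 -3 -2 1 -3 -3 5 -2 3 3 -2 -2 -2 -2 -2 0 5 -6 -1
K -1 -7 0 0 -6 -2 0 -2 6 -3 0 1 -1 1 4 0 0 -3 -4 -5
L -2 -7 -5 -4 2 -5 -3 3 -3 8 5 -3 -3 -2 -4 -3 -2 2 -2 -1
M -1 -6 -3 -3 0 -3 -3 3 0 5 8 -2 -2 -1 -1 -2 -1 2 -5 -3
N 0 -4 2 2 -4 1 2 -2 1 -3 -2 2 0 1 0 1 1 -2 -5 -3
P 1 -3 -1 -1 -6 0 0 -2 -1 -3 -2 0 7 0 0 1 0 -1 -7 -6
Q 0 -7 2 3 -6 -1 4 -2 1 -2 -1 1 0 5 2 -1 -1 -2 -6 -5
R -2 -5 -1 -1 -5 -3 2 -2 4 -4 -1 0 0 2 8 0 -1 -3 3 -5
S 1 0 0 0 -4 1 -1 -2 0 -3 -2 1 1 -1 0 2 2 -1 -3 -4
T 1 -3 0 0 -4 0 -1 0 0 -2 -1 1 0 -1 -1 2 3 0 -6 -3
V 0 -2 -3 -2 -1 -2 -3 5 -3 2 2 -2 -1 -2 -3 -1 0 5 -8 -3
W -7 -10 -8 -9 1 -9 -3 -6 -4 -2 -5 -5 -7 -6 3 -3 -6 -8 23 0
Y -4 1 -5 -5 9 -6 0 -1 -5 -1 -3 -3 -6 -5 -5 -4 -3 -3 0 13
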