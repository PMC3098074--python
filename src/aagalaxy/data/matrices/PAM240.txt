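# PAM240 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 240 substitution matrix, scale = ln(2)/3 = 0.231049
# Expected score = -0.923, Entropy = 0.379 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 2 -2 0 0 -4 1 -1 -1 -1 -2 -1 0 1 0 -2 1 1 0 -6 -4
C -2 12 -5 -6 -5 -4 -4 -2 -6 -6 -5 -4 -3 -6 -4 0 -2 -2 -8 0
D 0 -5 4 4 -6 1 1 -2 0 -4 -3 2 -1 2 -1 0 0 -2 -7 -4
E 0 -6 4 4 -6 0 1 -2 0 -3 -2 1 -1 3 -1 0 0 -2 -7 -4
F -4 -5 -6 -6 9 -5 -2 1 -5 2 0 -4 -5 -5 -5 -3 -3 -1 0 7
G 1 -4 1 0 -5 5 -2 -3 -2 -4 -3 0 -1 -1 -3 1 0 -1 -7 -5
H -1 -4 1 1 -2 -2 7 -3 0 -2 -2 2 0 3 2 -1 -1 -2 -3 0
I -1 -2 -2 -2 1 -3 -3 5 -2 2 2 -2 -2 -2 -2 -1 0 4 -5 -1
K -1 -6 0 0 -5 -2 0 -2 5 -3 0 1 -1 1 3 0 0 -3 -4 -5
L -2 -6 -4 -3 2 -4 -2 2 -3 6 4 -3 -3 -2 -3 -3 -2 2 -2 -1
M -1 -5 -3 -2 0 -3 -2 2 0 4 7 -2 -2 -1 0 -2 -1 2 -4 -3
N 0 -4 2 1 -4 0 2 -2 1 -3 -2 2 -1 1 0 1 0 -2 -4 -2
P 1 -3 -1 -1 -5 -1 0 -2 -1 -3 -2 -1 6 0 0 1 0 -1 -6 -5
Q 0 -6 2 3 -5 -1 3 -2 1 -2 -1 1 0 4 1 -1 -1 -2 -5 -4
R -2 -4 -1 -1 -5 -3 2 -2 3 -3 0 0 0 1 6 0 -1 -3 2 -4
S 1 0 0 0 -3 1 -1 -1 0 -3 -2 1 1 -1 0 2 1 -1 -3 -3
T 1 -2 0 0 -3 0 -1 0 0 -2 -1 0 0 -1 -1 1 3 0 -5 -3
V 0 -2 -2 -2 -1 -1 -2 4 -3 2 2 -2 -1 -2 -3 -1 0 4 -6 -3
W -6 -8 -7 -7 0 -7 -3 -5 -4 -2 -4 -4 -6 -5 2 -3 -5 -6 17 0
Y -4 0 -4 -4 7 -5 0 -1 -5 -1 -3 -2 -5 -4 -4 -3 -3 -3 0 10
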