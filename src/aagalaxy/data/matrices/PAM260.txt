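# PAM260 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 260 substitution matrix, scale = ln(2)/3 = 0.231049
# Expected score = -0.794, Entropy = 0.330 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 2 -2 0 0 -3 1 -1 0 -1 -2 -1 0 1 0 -1 1 1 0 -6 -3
C -2 12 -5 -5 -4 -3 -3 -2 -5 -6 -5 -3 -3 -5 -4 0 -2 -2 -7 0
D 0 -5 4 3 -5 1 1 -2 0 -4 -2 2 -1 2 -1 0 0 -2 -6 -4
E 0 -5 3 4 -5 0 1 -2 0 -3 -2 1 0 2 -1 0 0 -2 -7 -4
F -3 -4 -5 -5 9 -5 -2 1 -5 2 0 -3 -4 -4 -4 -3 -3 -1 0 7
G 1 -3 1 0 -5 5 -2 -2 -2 -4 -3 0 0 -1 -2 1 0 -1 -7 -5
H -1 -3 1 1 -2 -2 6 -2 0 -2 -2 2 0 3 2 -1 -1 -2 -3 0
I 0 -2 -2 -2 1 -2 -2 4 -2 2 2 -2 -2 -2 -2 -1 0 4 -5 -1
K -1 -5 0 0 -5 -2 0 -2 4 -3 0 1 -1 1 3 0 0 -2 -3 -4
L -2 -6 -4 -3 2 -4 -2 2 -3 6 4 -3 -2 -2 -3 -3 -2 2 -2 -1
M -1 -5 -2 -2 0 -3 -2 2 0 4 6 -2 -2 -1 0 -1 -1 2 -4 -2
N 0 -3 2 1 -3 0 2 -2 1 -3 -2 2 0 1 0 1 0 -2 -4 -2
P 1 -3 -1 0 -4 0 0 -2 -1 -2 -2 0 6 0 0 1 0 -1 -5 -5
Q 0 -5 2 2 -4 -1 3 -2 1 -2 -1 1 0 4 1 0 -1 -2 -5 -4
R -1 -4 -1 -1 -4 -2 2 -2 3 -3 0 0 0 1 6 0 -1 -2 2 -4
S 1 0 0 0 -3 1 -1 -1 0 -3 -1 1 1 0 0 1 1 -1 -2 -3
T 1 -2 0 0 -3 0 -1 0 0 -2 -1 0 0 -1 -1 1 2 0 -5 -3
V 0 -2 -2 -2 -1 -1 -2 4 -2 2 2 -2 -1 -2 -2 -1 0 4 -6 -2
W -6 -7 -6 -7 0 -7 -3 -5 -3 -2 -4 -4 -5 -5 2 -2 -5 -6 17 0
Y -3 0 -4 -4 7 -5 0 -1 -4 -1 -2 -2 -5 -4 -4 -3 -3 -2 0 10
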