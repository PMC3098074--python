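# PAM300 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 300 substitution matrix, scale = ln(2)/4 = 0.173287
# Expected score = -0.835, Entropy = 0.254 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 2 -2 0 0 -4 2 -1 0 -1 -2 -1 0 1 0 -1 1 1 0 -6 -4
C -2 15 -6 -6 -5 -4 -4 -3 -6 -7 -6 -4 -3 -6 -4 0 -2 -2 -9 1
D 0 -6 4 4 -6 1 1 -2 0 -4 -3 2 -1 2 -1 0 0 -2 -7 -5
E 0 -6 4 4 -6 0 1 -2 0 -4 -2 2 0 3 -1 0 0 -2 -8 -5
F -4 -5 -6 -6 11 -5 -2 1 -6 3 1 -4 -5 -5 -5 -4 -3 -1 1 9
G 2 -4 1 0 -5 5 -2 -3 -2 -4 -3 1 0 -1 -2 1 0 -1 -8 -6
H -1 -4 1 1 -2 -2 7 -2 0 -2 -2 2 0 3 2 -1 -1 -2 -3 0
I 0 -3 -2 -2 1 -3 -2 5 -2 3 3 -2 -2 -2 -2 -1 0 4 -6 -1
K -1 -6 0 0 -6 -2 0 -2 5 -3 0 1 -1 1 4 0 0 -2 -4 -5
L -2 -7 -4 -4 3 -4 -2 3 -3 7 4 -3 -3 -2 -3 -3 -2 2 -2 0
M -1 -6 -3 -2 1 -3 -2 3 0 4 6 -2 -2 -1 0 -2 -1 2 -5 -2
N 0 -4 2 2 -4 1 2 -2 1 -3 -2 2 0 1 0 1 0 -2 -5 -2
P 1 -3 -1 0 -5 0 0 -2 -1 -3 -2 0 6 0 0 1 1 -1 -6 -5
Q 0 -6 2 3 -5 -1 3 -2 1 -2 -1 1 0 4 2 0 -1 -2 -5 -4
R -1 -4 -1 -1 -5 -2 2 -2 4 -3 0 0 0 2 7 0 -1 -3 3 -5
S 1 0 0 0 -4 1 -1 -1 0 -3 -2 1 1 0 0 1 1 -1 -3 -3
T 1 -2 0 0 -3 0 -1 0 0 -2 -1 0 1 -1 -1 1 2 0 -6 -3
V 0 -2 -2 -2 -1 -1 -2 4 -2 2 2 -2 -1 -2 -3 -1 0 5 -7 -3
W -6 -9 -7 -8 1 -8 -3 -6 -4 -2 -5 -5 -6 -5 3 -3 -6 -7 22 0
Y -4 1 -5 -5 9 -6 0 -1 -5 0 -2 -2 -5 -4 -5 -3 -3 -3 0 12
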