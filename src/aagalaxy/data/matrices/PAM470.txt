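# PAM470 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 470 substitution matrix, scale = ln(2)/7 = 0.0990210
# Expected score = -0.520, Entropy = 0.0942 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 1 -2 1 1 -4 2 -1 0 0 -2 -1 1 1 0 -1 1 1 0 -7 -4
C -2 22 -5 -5 -4 -3 -4 -2 -6 -6 -6 -4 -3 -6 -4 0 -2 -2 -10 2
D 1 -5 3 3 -6 1 1 -2 1 -4 -2 2 0 2 0 1 0 -2 -8 -5
E 1 -5 3 3 -6 1 1 -2 1 -3 -2 2 0 2 0 1 0 -1 -8 -5
F -4 -4 -6 -6 14 -6 -2 2 -5 4 1 -4 -5 -5 -5 -4 -3 0 3 13
G 2 -3 1 1 -6 5 -1 -2 -1 -4 -2 1 1 0 -1 1 1 -1 -8 -6
H -1 -4 1 1 -2 -1 5 -2 1 -2 -1 1 0 3 2 0 0 -2 -3 0
I 0 -2 -2 -2 2 -2 -2 4 -2 4 3 -2 -1 -2 -2 -1 0 3 -5 0
K 0 -6 1 1 -5 -1 1 -2 4 -3 0 1 0 1 4 0 0 -2 -3 -5
L -2 -6 -4 -3 4 -4 -2 4 -3 8 5 -3 -2 -2 -3 -2 -1 3 -2 1
M -1 -6 -2 -2 1 -2 -1 3 0 5 4 -1 -1 -1 0 -1 0 2 -4 -1
N 1 -4 2 2 -4 1 1 -2 1 -3 -1 1 0 1 1 1 0 -1 -5 -3
P 1 -3 0 0 -5 1 0 -1 0 -2 -1 0 5 1 0 1 1 -1 -6 -5
Q 0 -6 2 2 -5 0 3 -2 1 -2 -1 1 1 3 2 0 0 -1 -5 -4
R -1 -4 0 0 -5 -1 2 -2 4 -3 0 1 0 2 6 0 0 -2 4 -5
S 1 0 1 1 -4 1 0 -1 0 -2 -1 1 1 0 0 1 1 -1 -4 -3
T 1 -2 0 0 -3 1 0 0 0 -1 0 0 1 0 0 1 1 0 -6 -3
V 0 -2 -2 -1 0 -1 -2 3 -2 3 2 -1 -1 -1 -2 -1 0 4 -7 -2
W -7 -10 -8 -8 3 -8 -3 -5 -3 -2 -4 -5 -6 -5 4 -4 -6 -7 35 2
Y -4 2 -5 -5 13 -6 0 0 -5 1 -1 -3 -5 -4 -5 -3 -3 -2 2 16
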