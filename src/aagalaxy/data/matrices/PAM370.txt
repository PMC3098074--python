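# PAM370 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 370 substitution matrix, scale = ln(2)/5 = 0.138629
# Expected score = -0.649, Entropy = 0.165 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 1 -2 1 1 -4 2 -1 0 -1 -2 -1 0 1 0 -1 1 1 0 -7 -4
C -2 18 -5 -6 -4 -3 -4 -2 -6 -6 -6 -4 -3 -6 -4 0 -2 -2 -9 1
D 1 -5 4 3 -6 1 1 -2 1 -4 -2 2 0 2 0 1 0 -2 -7 -5
E 1 -6 3 3 -6 1 1 -2 1 -3 -2 2 0 2 0 0 0 -2 -8 -5
F -4 -4 -6 -6 12 -5 -2 2 -6 3 1 -4 -5 -5 -5 -4 -3 0 2 11
G 2 -3 1 1 -5 5 -2 -2 -1 -4 -3 1 0 -1 -2 1 1 -1 -8 -6
H -1 -4 1 1 -2 -2 6 -2 1 -2 -2 2 0 3 2 0 -1 -2 -3 0
I 0 -2 -2 -2 2 -2 -2 4 -2 3 3 -2 -2 -2 -2 -1 0 4 -5 0
K -1 -6 1 1 -6 -1 1 -2 5 -3 0 1 -1 1 4 0 0 -2 -3 -5
L -2 -6 -4 -3 3 -4 -2 3 -3 7 5 -3 -3 -2 -3 -3 -1 3 -2 0
M -1 -6 -2 -2 1 -3 -2 3 0 5 5 -2 -2 -1 0 -1 0 2 -4 -2
N 0 -4 2 2 -4 1 2 -2 1 -3 -2 2 0 1 1 1 0 -1 -5 -3
P 1 -3 0 0 -5 0 0 -2 -1 -3 -2 0 6 1 0 1 1 -1 -6 -5
Q 0 -6 2 2 -5 -1 3 -2 1 -2 -1 1 1 3 2 0 0 -2 -5 -4
R -1 -4 0 0 -5 -2 2 -2 4 -3 0 1 0 2 6 0 0 -2 3 -4
S 1 0 1 0 -4 1 0 -1 0 -3 -1 1 1 0 0 1 1 -1 -3 -3
T 1 -2 0 0 -3 1 -1 0 0 -1 0 0 1 0 0 1 2 0 -6 -3
V 0 -2 -2 -2 0 -1 -2 4 -2 3 2 -1 -1 -2 -2 -1 0 4 -7 -2
W -7 -9 -7 -8 2 -8 -3 -5 -3 -2 -4 -5 -6 -5 3 -3 -6 -7 27 1
Y -4 1 -5 -5 11 -6 0 0 -5 0 -2 -3 -5 -4 -4 -3 -3 -2 1 14
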