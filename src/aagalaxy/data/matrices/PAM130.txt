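# PAM130 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 130 substitution matrix, scale = ln(2)/2 = 0.346574
# Expected score = -1.48, Entropy = 0.895 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 3 -3 0 0 -4 1 -2 -1 -2 -3 -2 0 1 -1 -3 1 1 0 -6 -4
C -3 9 -6 -6 -5 -4 -4 -3 -6 -7 -6 -4 -3 -6 -4 0 -3 -2 -8 -1
D 0 -6 5 3 -7 0 0 -3 -1 -5 -4 2 -2 1 -3 0 -1 -3 -7 -5
E 0 -6 3 5 -6 -1 0 -2 -1 -4 -3 1 -2 2 -3 -1 -1 -3 -8 -5
F -4 -5 -7 -6 7 -5 -2 0 -6 1 -1 -4 -5 -6 -5 -3 -4 -2 -1 4
G 1 -4 0 -1 -5 5 -3 -4 -3 -5 -4 0 -2 -2 -4 1 -1 -2 -7 -6
H -2 -4 0 0 -2 -3 7 -3 -1 -3 -3 2 -1 3 1 -2 -2 -3 -3 0
I -1 -3 -3 -2 0 -4 -3 5 -2 1 2 -2 -3 -3 -2 -2 0 3 -6 -2
K -2 -6 -1 -1 -6 -3 -1 -2 5 -4 0 1 -2 0 2 -1 0 -4 -5 -5
L -3 -7 -5 -4 1 -5 -3 1 -4 5 3 -3 -3 -2 -4 -4 -2 1 -2 -2
M -2 -6 -4 -3 -1 -4 -3 2 0 3 8 -3 -3 -1 -1 -2 -1 1 -5 -4
N 0 -4 2 1 -4 0 2 -2 1 -3 -3 4 -1 0 -1 1 0 -3 -4 -2
P 1 -3 -2 -2 -5 -2 -1 -3 -2 -3 -3 -1 6 0 -1 1 -1 -2 -6 -6
Q -1 -6 1 2 -6 -2 3 -3 0 -2 -1 0 0 5 1 -1 -2 -3 -6 -5
R -3 -4 -3 -3 -5 -4 1 -2 2 -4 -1 -1 -1 1 6 -1 -2 -3 1 -5
S 1 0 0 -1 -3 1 -2 -2 -1 -4 -2 1 1 -1 -1 3 2 -2 -2 -3
T 1 -3 -1 -1 -4 -1 -2 0 0 -2 -1 0 -1 -2 -2 2 4 0 -6 -3
V 0 -2 -3 -3 -2 -2 -3 3 -4 1 1 -3 -2 -3 -3 -2 0 5 -7 -3
W -6 -8 -7 -8 -1 -7 -3 -6 -5 -2 -5 -4 -6 -6 1 -2 -6 -7 12 -1
Y -4 -1 -5 -5 4 -6 0 -2 -5 -2 -4 -2 -6 -5 -5 -3 -3 -3 -1 8
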