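# PAM170 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 170 substitution matrix, scale = ln(2)/3 = 0.231049
# Expected score = -1.57, Entropy = 0.640 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 3 -3 0 0 -5 1 -3 -1 -2 -3 -2 0 1 -1 -3 2 2 0 -8 -5
C -3 13 -7 -8 -6 -5 -5 -3 -8 -9 -7 -5 -4 -8 -5 0 -3 -3 -10 0
D 0 -7 6 5 -8 0 0 -4 -1 -6 -4 3 -2 2 -3 0 -1 -4 -9 -6
E 0 -8 5 6 -8 0 0 -3 -1 -5 -3 2 -1 3 -2 -1 -1 -3 -10 -6
F -5 -6 -8 -8 10 -6 -3 1 -8 1 0 -5 -6 -7 -6 -4 -5 -2 -1 7
G 1 -5 0 0 -6 6 -4 -4 -3 -6 -4 0 -2 -2 -4 1 -1 -2 -9 -7
H -3 -5 0 0 -3 -4 9 -4 -1 -3 -4 2 -1 4 2 -2 -2 -3 -4 0
I -1 -3 -4 -3 1 -4 -4 7 -3 2 2 -3 -3 -3 -3 -2 0 5 -7 -2
K -2 -8 -1 -1 -8 -3 -1 -3 6 -4 1 1 -2 0 4 -1 0 -4 -5 -6
L -3 -9 -6 -5 1 -6 -3 2 -4 7 4 -4 -4 -2 -4 -4 -3 2 -3 -2
M -2 -7 -4 -3 0 -4 -4 2 1 4 10 -3 -3 -1 -1 -2 -1 2 -6 -4
N 0 -5 3 2 -5 0 2 -3 1 -4 -3 4 -1 0 -1 1 0 -3 -5 -3
P 1 -4 -2 -1 -6 -2 -1 -3 -2 -4 -3 -1 8 0 -1 1 0 -2 -8 -7
Q -1 -8 2 3 -7 -2 4 -3 0 -2 -1 0 0 6 1 -1 -2 -3 -7 -6
R -3 -5 -3 -2 -6 -4 2 -3 4 -4 -1 -1 -1 1 8 -1 -2 -4 2 -6
S 2 0 0 -1 -4 1 -2 -2 -1 -4 -2 1 1 -1 -1 3 2 -2 -3 -4
T 2 -3 -1 -1 -5 -1 -2 0 0 -3 -1 0 0 -2 -2 2 5 0 -7 -4
V 0 -3 -4 -3 -2 -2 -3 5 -4 2 2 -3 -2 -3 -4 -2 0 6 -9 -4
W -8 -10 -9 -10 -1 -9 -4 -7 -5 -3 -6 -5 -8 -7 2 -3 -7 -9 18 -1
Y -5 0 -6 -6 7 -7 0 -2 -6 -2 -4 -3 -7 -6 -6 -4 -4 -4 -1 12
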