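# PAM60 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 60 substitution matrix, scale = ln(2)/2 = 0.346574
# Expected score = -3.21, Entropy = 1.79 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 5 -5 -2 -1 -6 0 -5 -3 -5 -4 -3 -2 0 -3 -5 1 1 -1 -10 -6
C -5 9 -10 -10 -9 -7 -6 -4 -10 -11 -10 -7 -6 -10 -6 -1 -5 -4 -12 -2
D -2 -10 7 3 -11 -2 -2 -5 -2 -9 -7 2 -5 -1 -6 -2 -3 -6 -11 -8
E -1 -10 3 7 -10 -2 -3 -4 -3 -7 -5 0 -3 2 -6 -2 -4 -4 -12 -7
F -6 -9 -11 -10 8 -7 -4 -1 -10 -1 -2 -6 -7 -9 -7 -5 -6 -5 -3 3
G 0 -7 -2 -2 -7 6 -6 -7 -5 -8 -6 -1 -4 -5 -7 0 -3 -4 -11 -10
H -5 -6 -2 -3 -4 -6 8 -6 -4 -4 -7 1 -2 2 0 -4 -5 -5 -5 -2
I -3 -4 -5 -4 -1 -7 -6 7 -4 0 1 -4 -6 -5 -4 -4 -1 3 -10 -4
K -5 -10 -2 -3 -10 -5 -4 -4 6 -6 0 0 -4 -1 2 -2 -2 -6 -8 -7
L -4 -11 -9 -7 -1 -8 -4 0 -6 6 2 -5 -5 -3 -6 -6 -5 -1 -4 -5
M -3 -10 -7 -5 -2 -6 -7 1 0 2 10 -6 -6 -2 -2 -4 -2 0 -9 -7
N -2 -7 2 0 -6 -1 1 -4 0 -5 -6 6 -4 -2 -3 1 -1 -5 -6 -3
P 0 -6 -5 -3 -7 -4 -2 -6 -4 -5 -6 -4 7 -1 -2 0 -2 -4 -10 -10
Q -3 -10 -1 2 -9 -5 2 -5 -1 -3 -2 -2 -1 7 0 -3 -4 -5 -9 -8
R -5 -6 -6 -6 -7 -7 0 -4 2 -6 -2 -3 -2 0 8 -2 -4 -5 0 -8
S 1 -1 -2 -2 -5 0 -4 -4 -2 -6 -4 1 0 -3 -2 5 1 -4 -4 -5
T 1 -5 -3 -4 -6 -3 -5 -1 -2 -5 -2 -1 -2 -4 -4 1 6 -1 -9 -5
V -1 -4 -6 -4 -5 -4 -5 3 -6 -1 0 -5 -4 -5 -5 -4 -1 6 -11 -5
W -10 -12 -11 -12 -3 -11 -5 -10 -8 -4 -9 -6 -10 -9 0 -4 -9 -11 13 -3
Y -6 -2 -8 -7 3 -10 -2 -4 -7 -5 -7 -3 -10 -8 -8 -5 -5 -5 -3 9
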