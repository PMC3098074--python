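# PAM40 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 40 substitution matrix, scale = ln(2)/2 = 0.346574
# Expected score = -4.27, Entropy = 2.26 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 6 -6 -3 -2 -7 -1 -6 -4 -6 -5 -4 -3 -1 -3 -6 0 0 -2 -12 -7
C -6 9 -12 -12 -11 -8 -7 -5 -12 -13 -12 -9 -7 -12 -7 -2 -7 -5 -14 -3
D -3 -12 7 3 -13 -3 -3 -6 -4 -11 -9 2 -7 -2 -9 -3 -4 -7 -13 -10
E -2 -12 3 7 -12 -3 -4 -5 -4 -8 -6 -1 -5 2 -8 -4 -5 -6 -15 -8
F -7 -11 -13 -12 9 -8 -5 -2 -12 -2 -3 -8 -9 -11 -8 -6 -8 -7 -4 2
G -1 -8 -3 -3 -8 6 -8 -9 -6 -9 -7 -2 -5 -6 -8 -1 -5 -5 -13 -12
H -6 -7 -3 -4 -5 -8 9 -8 -5 -5 -9 1 -3 1 -1 -5 -6 -6 -6 -3
I -4 -5 -6 -5 -2 -9 -8 8 -5 -1 0 -4 -7 -7 -5 -6 -2 2 -12 -5
K -6 -12 -4 -4 -12 -6 -5 -5 6 -7 -1 0 -6 -2 1 -3 -2 -8 -10 -8
L -5 -13 -11 -8 -2 -9 -5 -1 -7 7 1 -6 -6 -4 -8 -7 -6 -2 -5 -6
M -4 -12 -9 -6 -3 -7 -9 0 -1 1 11 -7 -7 -3 -3 -5 -3 -1 -11 -10
N -3 -9 2 -1 -8 -2 1 -4 0 -6 -7 7 -5 -3 -5 0 -1 -7 -7 -4
P -1 -7 -7 -5 -9 -5 -3 -7 -6 -6 -7 -5 8 -2 -3 -1 -3 -5 -12 -12
Q -3 -12 -2 2 -11 -6 1 -7 -2 -4 -3 -3 -2 8 -1 -4 -5 -6 -11 -10
R -6 -7 -9 -8 -8 -8 -1 -5 1 -8 -3 -5 -3 -1 8 -2 -5 -7 -1 -9
S 0 -2 -3 -4 -6 -1 -5 -6 -3 -7 -5 0 -1 -4 -2 6 1 -5 -4 -6
T 0 -7 -4 -5 -8 -5 -6 -2 -2 -6 -3 -1 -3 -5 -5 1 7 -2 -11 -6
V -2 -5 -7 -6 -7 -5 -6 2 -8 -2 -1 -7 -5 -6 -7 -5 -2 7 -14 -6
W -12 -14 -13 -15 -4 -13 -6 -12 -10 -5 -11 -7 -12 -11 -1 -4 -11 -14 13 -4
Y -7 -3 -10 -8 2 -12 -3 -5 -8 -6 -10 -4 -12 -10 -9 -6 -6 -6 -4 10
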