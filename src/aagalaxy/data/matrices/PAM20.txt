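# PAM20 substitution matrix, rounded (20x20, canonical residue order)
# This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
# PAM 20 substitution matrix, scale = ln(2)/2 = 0.346574
# Expected score = -6.18, Entropy = 2.95 bits
 A C D E F G H I K L M N P Q R S T V W Y
A 6 -8 -4 -3 -9 -3 -8 -6 -8 -7 -6 -5 -2 -5 -8 -1 -1 -3 -16 -9
C -8 10 -16 -16 -15 -11 -8 -7 -16 -17 -16 -13 -9 -16 -9 -4 -9 -7 -18 -5
D -4 -16 8 2 -17 -4 -5 -9 -6 -15 -13 1 -9 -4 -12 -5 -6 -9 -17 -13
E -3 -16 2 8 -16 -5 -6 -6 -5 -10 -8 -3 -7 0 -11 -5 -7 -8 -19 -9
F -9 -15 -17 -16 9 -10 -7 -3 -16 -4 -5 -10 -11 -15 -10 -7 -10 -9 -6 1
G -3 -11 -4 -5 -10 7 -10 -13 -8 -12 -10 -4 -7 -8 -11 -3 -7 -7 -17 -16
H -8 -8 -5 -6 -7 -10 9 -11 -8 -7 -13 -1 -5 0 -3 -7 -8 -7 -8 -4
I -6 -7 -9 -6 -3 -13 -11 9 -7 -2 -2 -6 -10 -9 -6 -8 -3 1 -16 -7
K -8 -16 -6 -5 -16 -8 -8 -7 7 -9 -3 -2 -8 -4 -1 -5 -4 -10 -14 -10
L -7 -17 -15 -10 -4 -12 -7 -2 -9 7 0 -8 -8 -6 -10 -9 -8 -3 -7 -8
M -6 -16 -13 -8 -5 -10 -13 -2 -3 0 11 -11 -9 -5 -5 -6 -5 -2 -15 -13
N -5 -13 1 -3 -10 -4 -1 -6 -2 -8 -11 8 -7 -5 -7 -1 -3 -9 -9 -5
P -2 -9 -9 -7 -11 -7 -5 -10 -8 -8 -9 -7 8 -4 -5 -3 -5 -7 -16 -16
Q -5 -16 -4 0 -15 -8 0 -9 -4 -6 -5 -5 -4 9 -2 -6 -7 -8 -15 -14
R -8 -9 -12 -11 -10 -11 -3 -6 -1 -10 -5 -7 -5 -2 9 -4 -8 -9 -3 -11
S -1 -4 -5 -5 -7 -3 -7 -8 -5 -9 -6 -1 -3 -6 -4 7 0 -8 -6 -8
T -1 -9 -6 -7 -10 -7 -8 -3 -4 -8 -5 -3 -5 -7 -8 0 7 -4 -15 -7
V -3 -7 -9 -8 -9 -7 -7 1 -10 -3 -2 -9 -7 -8 -9 -8 -4 7 -18 -8
W -16 -18 -17 -19 -6 -17 -8 -16 -14 -7 -15 -9 -16 -15 -3 -6 -15 -18 13 -6
Y -9 -5 -13 -9 1 -16 -4 -7 -10 -8 -13 -5 -16 -14 -11 -8 -7 -8 -6 10
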