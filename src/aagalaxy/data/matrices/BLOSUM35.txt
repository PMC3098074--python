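# BLOSUM35 substitution matrix, rounded (20x20, canonical residue order)
# Matrix made by matblas from blosum35.iij
# BLOSUM Clustered Scoring Matrix in 1/4 Bit Units
# Blocks Database = /data/blocks_5.0/blocks.dat
# Cluster Percentage: >= 35
# Entropy =   0.2111, Expected =  -0.1550
 A C D E F G H I K L M N P Q R S T V W Y
A 5 -2 -1 -1 -2 0 -2 -1 0 -2 0 -1 -2 0 -1 1 0 0 -2 -1
C -2 15 -3 -1 -4 -3 -4 -4 -2 -2 -4 -1 -4 -3 -3 -3 -1 -2 -5 -5
D -1 -3 8 2 -3 -2 0 -3 -1 -2 -3 1 -1 -1 -1 -1 -1 -2 -3 -2
E -1 -1 2 6 -3 -2 -1 -3 1 -1 -2 -1 0 2 -1 0 -1 -2 -1 -1
F -2 -4 -3 -3 8 -3 -3 1 -1 2 0 -1 -4 -4 -1 -1 -1 1 1 3
G 0 -3 -2 -2 -3 7 -2 -3 -1 -3 -1 1 -2 -2 -2 1 -2 -3 -1 -2
H -2 -4 0 -1 -3 -2 12 -3 -2 -2 1 1 -1 -1 -1 -1 -2 -4 -4 0
I -1 -4 -3 -3 1 -3 -3 5 -2 2 1 -1 -1 -2 -3 -2 -1 4 -1 0
K 0 -2 -1 1 -1 -1 -2 -2 5 -2 0 0 0 0 2 0 0 -2 0 -1
L -2 -2 -2 -1 2 -3 -2 2 -2 5 3 -2 -3 -2 -2 -2 0 2 0 0
M 0 -4 -3 -2 0 -1 1 1 0 3 6 -1 -3 -1 0 -1 0 1 1 0
N -1 -1 1 -1 -1 1 1 -1 0 -2 -1 7 -2 1 -1 0 0 -2 -2 -2
P -2 -4 -1 0 -4 -2 -1 -1 0 -3 -3 -2 10 0 -2 -2 0 -3 -4 -3
Q 0 -3 -1 2 -4 -2 -1 -2 0 -2 -1 1 0 7 2 0 0 -3 -1 0
R -1 -3 -1 -1 -1 -2 -1 -3 2 -2 0 -1 -2 2 8 -1 -2 -1 0 0
S 1 -3 -1 0 -1 1 -1 -2 0 -2 -1 0 -2 0 -1 4 2 -1 -2 -1
T 0 -1 -1 -1 -1 -2 -2 -1 0 0 0 0 0 0 -2 2 5 1 -2 -2
V 0 -2 -2 -2 1 -3 -4 4 -2 2 1 -2 -3 -3 -1 -1 1 5 -2 0
W -2 -5 -3 -1 1 -1 -4 -1 0 0 1 -2 -4 -1 0 -2 -2 -2 16 3
Y -1 -5 -2 -1 3 -2 0 0 -1 0 0 -2 -3 0 0 -1 -2 0 3 8
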