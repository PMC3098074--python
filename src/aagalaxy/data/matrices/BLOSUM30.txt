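# BLOSUM30 substitution matrix, rounded (20x20, canonical residue order)
# Matrix made by matblas from blosum30.iij
# BLOSUM Clustered Scoring Matrix in 1/5 Bit Units
# Blocks Database = /data/blocks_5.0/blocks.dat
# Cluster Percentage: >= 30
# Entropy =   0.1424, Expected =  -0.1074
 A C D E F G H I K L M N P Q R S T V W Y
A 4 -3 0 0 -2 0 -2 0 0 -1 1 0 -1 1 -1 1 1 1 -5 -4
C -3 17 -3 1 -3 -4 -5 -2 -3 0 -2 -1 -3 -2 -2 -2 -2 -2 -2 -6
D 0 -3 9 1 -5 -1 -2 -4 0 -1 -3 1 -1 -1 -1 0 -1 -2 -4 -1
E 0 1 1 6 -4 -2 0 -3 2 -1 -1 -1 1 2 -1 0 -2 -3 -1 -2
F -2 -3 -5 -4 10 -3 -3 0 -1 2 -2 -1 -4 -3 -1 -1 -2 1 1 3
G 0 -4 -1 -2 -3 8 -3 -1 -1 -2 -2 0 -1 -2 -2 0 -2 -3 1 -3
H -2 -5 -2 0 -3 -3 14 -2 -2 -1 2 -1 1 0 -1 -1 -2 -3 -5 0
I 0 -2 -4 -3 0 -1 -2 6 -2 2 1 0 -3 -2 -3 -1 0 4 -3 -1
K 0 -3 0 2 -1 -1 -2 -2 4 -2 2 0 1 0 1 0 -1 -2 -2 -1
L -1 0 -1 -1 2 -2 -1 2 -2 4 2 -2 -3 -2 -2 -2 0 1 -2 3
M 1 -2 -3 -1 -2 -2 2 1 2 2 6 0 -4 -1 0 -2 0 0 -3 -1
N 0 -1 1 -1 -1 0 -1 0 0 -2 0 8 -3 -1 -2 0 1 -2 -7 -4
P -1 -3 -1 1 -4 -1 1 -3 1 -3 -4 -3 11 0 -1 -1 0 -4 -3 -2
Q 1 -2 -1 2 -3 -2 0 -2 0 -2 -1 -1 0 8 3 -1 0 -3 -1 -1
R -1 -2 -1 -1 -1 -2 -1 -3 1 -2 0 -2 -1 3 8 -1 -3 -1 0 0
S 1 -2 0 0 -1 0 -1 -1 0 -2 -2 0 -1 -1 -1 4 2 -1 -3 -2
T 1 -2 -1 -2 -2 -2 -2 0 -1 0 0 1 0 0 -3 2 5 1 -5 -1
V 1 -2 -2 -3 1 -3 -3 4 -2 1 0 -2 -4 -3 -1 -1 1 5 -3 1
W -5 -2 -4 -1 1 1 -5 -3 -2 -2 -3 -7 -3 -1 0 -3 -5 -3 20 5
Y -4 -6 -1 -2 3 -3 0 -1 -1 3 -1 -4 -2 -1 0 -2 -1 1 5 9
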