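# BLOSUM85 substitution matrix, rounded (20x20, canonical residue order)
# Matrix made by matblas from blosum85.iij
# BLOSUM Clustered Scoring Matrix in 1/2 Bit Units
# Blocks Database = /data/blocks_5.0/blocks.dat
# Cluster Percentage: >= 85
# Entropy =   1.0805, Expected =  -0.8153
 A C D E F G H I K L M N P Q R S T V W Y
A 5 -1 -2 -1 -3 0 -2 -2 -1 -2 -2 -2 -1 -1 -2 1 0 -1 -3 -3
C -1 9 -5 -5 -3 -4 -5 -2 -4 -2 -2 -4 -4 -4 -4 -2 -2 -1 -4 -3
D -2 -5 7 1 -4 -2 -2 -5 -1 -5 -4 1 -2 -1 -2 -1 -2 -4 -6 -4
E -1 -5 1 6 -4 -3 -1 -4 0 -4 -3 -1 -2 2 -1 -1 -1 -3 -4 -4
F -3 -3 -4 -4 7 -4 -2 -1 -4 0 -1 -4 -4 -4 -4 -3 -3 -1 0 3
G 0 -4 -2 -3 -4 6 -3 -5 -2 -5 -4 -1 -3 -3 -3 -1 -2 -4 -4 -5
H -2 -5 -2 -1 -2 -3 8 -4 -1 -3 -3 0 -3 1 0 -1 -2 -4 -3 2
I -2 -2 -5 -4 -1 -5 -4 5 -3 1 1 -4 -4 -4 -4 -3 -1 3 -3 -2
K -1 -4 -1 0 -4 -2 -1 -3 6 -3 -2 0 -2 1 2 -1 -1 -3 -5 -3
L -2 -2 -5 -4 0 -5 -3 1 -3 4 2 -4 -4 -3 -3 -3 -2 0 -3 -2
M -2 -2 -4 -3 -1 -4 -3 1 -2 2 7 -3 -3 0 -2 -2 -1 0 -2 -2
N -2 -4 1 -1 -4 -1 0 -4 0 -4 -3 7 -3 0 -1 0 0 -4 -5 -3
P -1 -4 -2 -2 -4 -3 -3 -4 -2 -4 -3 -3 8 -2 -2 -1 -2 -3 -5 -4
Q -1 -4 -1 2 -4 -3 1 -4 1 -3 0 0 -2 6 1 -1 -1 -3 -3 -2
R -2 -4 -2 -1 -4 -3 0 -4 2 -3 -2 -1 -2 1 6 -1 -2 -3 -4 -3
S 1 -2 -1 -1 -3 -1 -1 -3 -1 -3 -2 0 -1 -1 -1 5 1 -2 -4 -2
T 0 -2 -2 -1 -3 -2 -2 -1 -1 -2 -1 0 -2 -1 -2 1 5 0 -4 -2
V -1 -1 -4 -3 -1 -4 -4 3 -3 0 0 -4 -3 -3 -3 -2 0 5 -3 -2
W -3 -4 -6 -4 0 -4 -3 -3 -5 -3 -2 -5 -5 -3 -4 -4 -4 -3 11 2
Y -3 -3 -4 -4 3 -5 2 -2 -3 -2 -2 -3 -4 -2 -3 -2 -2 -2 2 7
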