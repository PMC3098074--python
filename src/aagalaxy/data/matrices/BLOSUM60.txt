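# BLOSUM60 substitution matrix, rounded (20x20, canonical residue order)
# Matrix made by matblas from blosum60.iij
# BLOSUM Clustered Scoring Matrix in 1/2 Bit Units
# Blocks Database = /data/blocks_5.0/blocks.dat
# Cluster Percentage: >= 60
# Entropy =   0.6603, Expected =  -0.4917
 A C D E F G H I K L M N P Q R S T V W Y
A 4 0 -2 -1 -2 0 -2 -1 -1 -1 -1 -1 -1 -1 -1 1 0 0 -3 -2
C 0 9 -3 -3 -2 -2 -3 -1 -3 -1 -1 -2 -3 -3 -3 -1 -1 -1 -2 -2
D -2 -3 6 2 -3 -1 -1 -3 -1 -3 -3 1 -1 0 -1 0 -1 -3 -4 -3
E -1 -3 2 5 -3 -2 0 -3 1 -3 -2 0 -1 2 0 0 -1 -2 -3 -2
F -2 -2 -3 -3 6 -3 -1 0 -3 0 0 -3 -4 -3 -3 -2 -2 -1 1 3
G 0 -2 -1 -2 -3 6 -2 -3 -1 -4 -2 0 -2 -2 -2 0 -2 -3 -2 -3
H -2 -3 -1 0 -1 -2 7 -3 -1 -3 -1 1 -2 1 0 -1 -2 -3 -2 2
I -1 -1 -3 -3 0 -3 -3 4 -3 2 1 -3 -3 -3 -3 -2 -1 3 -2 -1
K -1 -3 -1 1 -3 -1 -1 -3 4 -2 -1 0 -1 1 2 0 -1 -2 -3 -2
L -1 -1 -3 -3 0 -4 -3 2 -2 4 2 -3 -3 -2 -2 -2 -1 1 -2 -1
M -1 -1 -3 -2 0 -2 -1 1 -1 2 5 -2 -2 0 -1 -1 -1 1 -1 -1
N -1 -2 1 0 -3 0 1 -3 0 -3 -2 6 -2 0 0 1 0 -3 -4 -2
P -1 -3 -1 -1 -4 -2 -2 -3 -1 -3 -2 -2 7 -1 -2 -1 -1 -2 -4 -3
Q -1 -3 0 2 -3 -2 1 -3 1 -2 0 0 -1 5 1 0 -1 -2 -2 -1
R -1 -3 -1 0 -3 -2 0 -3 2 -2 -1 0 -2 1 5 -1 -1 -2 -3 -2
S 1 -1 0 0 -2 0 -1 -2 0 -2 -1 1 -1 0 -1 4 1 -2 -3 -2
T 0 -1 -1 -1 -2 -2 -2 -1 -1 -1 -1 0 -1 -1 -1 1 4 0 -2 -2
V 0 -1 -3 -2 -1 -3 -3 3 -2 1 1 -3 -2 -2 -2 -2 0 4 -3 -1
W -3 -2 -4 -3 1 -2 -2 -2 -3 -2 -1 -4 -4 -2 -3 -3 -2 -3 10 2
Y -2 -2 -3 -2 3 -3 2 -1 -2 -1 -1 -2 -3 -1 -2 -2 -2 -1 2 6
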