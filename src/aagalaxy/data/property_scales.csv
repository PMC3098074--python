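# 17 scalar physicochemical property scales, canonical residue order.
# 2chrg  : charge (K,R = +1; D,E = -1; others 0) -- constructed
# 3achrg : absolute charge |2chrg| -- constructed
# 5arom  : aromaticity (F,W,Y = 1; others 0) -- constructed
# All other rows are AAindex entries (via the seqinr aaindex dataset),
# chosen as representative scales of the property families suggested by
# the short names (volume, accessibility, hydrophobicity variants,
# bulkiness, secondary-structure propensities, turn/bend, mass).
# 1rsvol : Volume (Grantham, 1974) [GRAR740103]
# 4awrat : Average accessible surface area (Janin et al., 1978) [JANJ780101]
# 6hdrp  : Hydropathy index (Kyte-Doolittle, 1982) [KYTJ820101]
# 7kbulk : Bulkiness (Zimmerman et al., 1968) [ZIMJ680102]
# 8khdr2 : Hydrophilicity value (Hopp-Woods, 1981) [HOPT810101]
# 9khdr3 : Consensus normalized hydrophobicity scale (Eisenberg, 1984) [EISD840101]
# 10khdr4: Hydrophobic parameter pi (Fauchere-Pliska, 1983) [FAUJ830101]
# 11kbpr1: Normalized frequency of beta-sheet (Chou-Fasman, 1978b) [CHOP780202]
# 12kbpr2: Conformational preference for all beta-strands (Lifson-Sander, 1979) [LIFS790101]
# 13kaprf: Normalized frequency of alpha-helix (Chou-Fasman, 1978b) [CHOP780201]
# 14kbnd1: Normalized frequency of beta-turn (Chou-Fasman, 1978b) [CHOP780203]
# 15kbnd2: Normalized frequency of reverse turn, with weights (Levitt, 1978) [LEVM780103]
# 16hydro: Transfer energy, organic solvent/water (Nozaki-Tanford, 1971) [NOZY710101]
# 17mass : Molecular weight (Fasman, 1976) [FASG760101]
property,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
1rsvol,31.0,55.0,54.0,83.0,132.0,3.0,96.0,111.0,119.0,111.0,105.0,56.0,32.5,85.0,124.0,32.0,61.0,84.0,170.0,136.0
2chrg,0,0,-1,-1,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0
3achrg,0,0,1,1,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0
4awrat,27.8,15.5,60.6,68.2,25.5,24.5,50.7,22.8,103.0,27.6,33.5,60.1,51.5,68.7,94.7,42.0,45.0,23.7,34.7,55.2
5arom,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1
6hdrp,1.8,2.5,-3.5,-3.5,2.8,-0.4,-3.2,4.5,-3.9,3.8,1.9,-3.5,-1.6,-3.5,-4.5,-0.8,-0.7,4.2,-0.9,-1.3
7kbulk,11.50,13.46,11.68,13.57,19.80,3.40,13.69,21.40,15.71,21.40,16.25,12.82,17.43,14.45,14.28,9.47,15.77,21.57,21.67,18.03
8khdr2,-0.5,-1.0,3.0,3.0,-2.5,0.0,-0.5,-1.8,3.0,-1.8,-1.3,0.2,0.0,0.2,3.0,0.3,-0.4,-1.5,-3.4,-2.3
9khdr3,0.25,0.04,-0.72,-0.62,0.61,0.16,-0.40,0.73,-1.10,0.53,0.26,-0.64,-0.07,-0.69,-1.76,-0.26,-0.18,0.54,0.37,0.02
10khdr4,0.31,1.54,-0.77,-0.64,1.79,0.00,0.13,1.80,-0.99,1.70,1.23,-0.60,0.72,-0.22,-1.01,-0.04,0.26,1.22,2.25,0.96
11kbpr1,0.83,1.19,0.54,0.37,1.38,0.75,0.87,1.60,0.74,1.30,1.05,0.89,0.55,1.10,0.93,0.75,1.19,1.70,1.37,1.47
12kbpr2,0.92,1.16,0.48,0.61,1.25,0.61,0.93,1.81,0.70,1.30,1.19,0.60,0.40,0.95,0.93,0.82,1.12,1.81,1.54,1.53
13kaprf,1.42,0.70,1.01,1.51,1.13,0.57,1.00,1.08,1.16,1.21,1.45,0.67,0.57,1.11,0.98,0.77,0.83,1.06,1.08,0.69
14kbnd1,0.74,0.96,1.52,0.95,0.66,1.56,0.95,0.47,1.19,0.50,0.60,1.46,1.56,0.96,1.01,1.43,0.98,0.59,0.60,1.14
15kbnd2,0.77,0.81,1.41,0.99,0.59,1.64,0.68,0.51,0.96,0.58,0.41,1.28,1.91,0.98,0.88,1.32,1.04,0.47,0.76,1.05
16hydro,0.5,0.0,0.0,0.0,2.5,0.0,0.5,1.8,0.0,1.8,1.3,0.0,0.0,0.0,0.0,0.0,0.4,1.5,3.4,2.3
17mass,89.09,121.15,133.10,147.13,165.19,75.07,155.16,131.17,146.19,131.17,149.21,132.12,115.13,146.15,174.20,105.09,119.12,117.15,204.24,181.19
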