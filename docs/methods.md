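# Methods

## Model

A substitution matrix *S* is a symmetric 20×20 table of log-odds scores.
Being symmetric, its SVD coincides with its eigendecomposition: singular
values are the absolute eigenvalues, and a component's left and right
singular vectors are equal for positive eigenvalues and opposed for
negative ones. Only the positive components can be realized as real
vectors, so the embedding keeps, for each eigenvalue λ<sub>K</sub> > 0,
the coordinates *A*<sub>aK</sub> = *U*<sub>Ka</sub>·√λ<sub>K</sub>. The sum
of all squared singular values (kept and dropped) equals ‖S‖²<sub>F</sub>,
which makes the quality index

  Q(S, Ŝ) = 100 · (1 − ‖S − Ŝ‖²<sub>F</sub> / ‖S‖²<sub>F</sub>)

interpretable for the raw truncation as the percentage of squared
Frobenius mass carried by the retained components. The squared form of the
ratio was fixed by validating candidate forms against the published
reconstruction-quality series for the canonical rounded PAM fixtures,
which it reproduces at printed precision (94.7 / 70.6 / 28.5 for
PAM500 / PAM160 / PAM10); the unsquared form is off by tens of points and
is ruled out.

Substitution matrices have negative eigenvalues (they are not Gram
matrices), increasingly so at short evolutionary distances; this is why
raw reconstruction quality falls from ~95% (PAM500) to ~29% (PAM10).
Centering the matrix — subtracting the arithmetic mean of all 400 cells —
largely removes the offending mass without changing the centered residue
cloud (the "galaxy"): shifting a Gram matrix by a constant changes only
the translation of the generating points, so the centered galaxy is a
shift-invariant signature of the matrix.

### Shift + translation refinement

The refinement model is ŝ<sub>ab</sub> = (A<sub>a</sub>+T)·(A<sub>b</sub>+T) + shift,
with the translation *T* and scalar *shift* minimizing the summed squared
error. Eliminating the shift at its optimum (shift = s̄ − ‖c‖², where
c = t + T and t is the vector centroid) makes the model exactly linear in
*c*, so the optimum is obtained from the normal equations
(Ã<sup>T</sup>Ã)c = Ã<sup>T</sup>g/20 in the centered vector coordinates
Ã, where g holds the centered row sums of *S*. No iteration or
approximation is involved; a pseudo-inverse fallback (flagged on the
result) handles rank-deficient vector sets. Because (T=0, shift=0) lies in
the feasible family, the refined quality can never fall below the raw
reconstruction on the same vectors.

### Property axes

A scalar property p (centered, scaled to unit Euclidean norm — *not* unit
variance, so the weights' self-sum is exactly 1) is mapped to the axis
n̂ ∝ Σ<sub>a</sub> p<sub>a</sub>Ã<sub>a</sub> with scale λ = ‖Σ<sub>a</sub>
p<sub>a</sub>Ã<sub>a</sub>‖, the least-squares optimum of
Σ<sub>a</sub>‖λp<sub>a</sub>n̂ − Ã<sub>a</sub>‖². Its contribution is
100·λ²/Σ<sub>a</sub>‖Ã<sub>a</sub>‖², bounded by the leading component's
share 100·w₁/Σ<sub>K</sub>w<sub>K</sub> (≈19% for BLOSUM62). For a random
centered unit property the expected contribution is 100/19 ≈ 5.26%
(the squared cosine of a random direction in the 19-dimensional centered
subspace), which matches the measured 5.2 ± 1.4 baseline; note this also
means a one-dimensional galaxy has a random baseline of ~5.26%, not 100%.

### Distances

d = s<sub>aa</sub> + s<sub>bb</sub> − 2s<sub>ab</sub> (and its square
root) converts similarities to putative distances; for a true Gram matrix
the square-root form gives exactly the Euclidean inter-point distances.
The triangle audit reports both conventions over the C(20,3) = 1140
unordered triplets: how many triplets have any failing inequality, and how
many of the 3·1140 individual inequalities fail. On the canonical rounded
PAM fixtures the square-root distance is fully metric up to PAM210; above
that up to ~7.5% of triplets but at most ~2.5% of individual inequalities
fail — the published "at most 3%" figure is only consistent with the
per-inequality convention, which the acceptance checks therefore use.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `tol` (decompose) | 1e-10 | components with w ≤ tol·w₁ are rank noise |
| axis sign | largest coordinate positive | resolves SVD sign ambiguity reproducibly |
| k-means | k-means++, 50 restarts, seed 0 | best-of-restarts partition, deterministic |
| superposition | improper maps allowed | SVD axes have arbitrary signs; disable via `allow_reflection=False` |
| galaxy radius | mean (not RMS) distance from centroid | |
| stress/anti-correlation fits | 20 restarts, seeded | L-BFGS / SMACOF local optimization |
| random baseline | n = 1000 draws | standard-normal 20-vectors, centered + normalized |

## Fixtures and their limits

The bundled matrices are the canonical **rounded** NCBI sets: BLOSUM
30–90 (step 5), 62 and 100 (BLOSUM95 is absent from the public
collections this package draws on) and PAM 10–500 (step 10), with the
original matblas/"pam" headers carrying the relative entropy and the
fractional-bit scale of each file. The non-rounded BLOSUM tables of the
BLOCKS database are not redistributable here; `load_matrix(...,
rounded=False)` says so explicitly.

Rounding matters at the margins. Against published values computed from
the non-rounded BLOSUM tables: raw BLOSUM62 quality is 77.8 (rounded)
vs 75.7 (non-rounded); centered qualities agree to ~0.1; the k-means
partition of the BLOSUM62 galaxy reproduces the published rows for
k = 2, 3 but at k = 4, 5 the global optimum moves C from the aliphatic
cluster into the small/polar cluster (300 restarts confirm this is not a
local-optimum artifact); and the consensus of {H, R, V} is R rather than
the published T — with these vectors T is not among the five residues
nearest the column centroid, for any bundled matrix.

Cross-series statistics follow the sources' own scales: BLOSUM series
statistics are computed in bit units (the non-rounded originals were
published in bits; rounded fixtures are rescaled via their header scale),
while PAM series statistics use the native printed integer scale, which is
how those matrices circulate. With these conventions the mean↔entropy and
radius↔entropy correlations and both radius-growth figures agree with the
published values to within 0.005 / a few percent. On a common bit scale
the PAM galaxies are larger than their BLOSUM counterparts for
PAM100/120/160 ↔ BLOSUM90/80/60, but the PAM250 ↔ BLOSUM45 pair inverts
(1.49 vs 1.61 bits) — worth knowing before comparing radii across series.

The published centered-PAM quality/correlation triple (96.8/89.5/93.9 and
0.985/0.943/0.923) could not be reproduced from the canonical PAM
fixtures by any centering variant tried (plain, double centering), even
though the raw triple reproduces exactly and the identical procedure
reproduces the centered BLOSUM values; the honest recomputed values are
99.2/96.3/93.7 (0.998/0.990/0.981).

## Property table provenance

`property_scales.csv` constructs charge (K,R = +1; D,E = −1), absolute
charge and aromaticity (F,W,Y = 1) exactly as the analysis defines them,
and fills the remaining 14 slots with documented AAindex accessions
(volume, accessibility, four hydrophobicity scales, bulkiness,
secondary-structure and turn propensities, transfer energy, molecular
weight). The original study's exact scale selection (including nine
Kidera-derived factors) is not publicly recoverable, so per-scale
contribution values are only directly comparable for the constructed
scales — charge lands on 6.0% for BLOSUM62, aromaticity on 13.7%
(published 14.2 with non-rounded vectors), volume 12.8 (12.7), molecular
weight 11.5 (11.6).

## What the synthetic generators do and do not emulate

`random_gram` produces exact low-rank Gram matrices with a known shift —
ideal oracles for the decomposition, refinement and superposition code,
but free of rounding noise and negative eigenvalues, so passing those
tests says nothing about behaviour on real (indefinite) score matrices;
the fixture-based tests cover that. `random_pseudo_matrix` draws a
symmetric Dirichlet joint distribution over the 210 unordered pairs,
yielding log-odds matrices with nonnegative mutual information and
negative expected score; it spans the independence-to-covariation range
but does not model evolutionary time or realistic residue frequencies.

## Degenerate inputs and tie-breaks

Zero-variance inputs raise (correlation of a constant table, constant
property scales, all-gap alignment columns, series with identical
matrices). Consensus ties are broken toward the earlier residue in the
canonical order A,C,D,…,Y and logged. Cluster ids are relabelled by first
appearance along the canonical order so partitions are reproducible.
Distance conversions reject negative squared distances by naming the
offending pairs; the vector metric never produces them.
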