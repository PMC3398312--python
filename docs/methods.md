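# Methods

This note documents the models and procedures implemented in
`crossprofiler`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic study
conditions do and do not demonstrate.

## Backbone geometry and segments

Chains are reduced to their N/CA/C trace. φ of residue *k* is the torsion
C(k−1)–N(k)–CA(k)–C(k) and ψ is N(k)–CA(k)–C(k)–N(k+1), IUPAC sign, range
(−180°, 180°]; the implementation is cross-checked in the tests against an
independent crystallographic library (gemmi). A dihedral is undefined when
it touches a chain terminus, a residue missing a backbone atom, or a chain
break, detected as consecutive CA–CA distance > 4.5 Å — a deliberately
generous bound on trans-peptide geometry (ideal ≈ 3.80 Å).

Sliding L-residue windows (default L = 15; 9 also standard) advance one
residue at a time and may overlap. A window is kept only if all 2L of its
angles are defined; since the terminal φ/ψ of a window come from flanking
residues, windows touching chain ends or breaks are dropped rather than
imputed. This is the conservative resolution of an under-specified corner:
imputing terminal angles would inject arbitrary geometry into the
clustering space.

Only (φ, ψ) enter the structural description; ω is fixed at its trans value
in the synthetic builder and ignored during classification. A config
placeholder exists should cis-proline-aware classification ever be needed.

The synthetic backbone builder places atoms by sequential internal
coordinates (NeRF) with fixed ideal bond lengths (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å), bond angles (111.2°, 116.2°, 121.7°) and ω = 180°.
Because geometry is ideal, recomputing dihedrals recovers the inputs to
~1e-13 degrees, giving an exact round-trip oracle for both the torsion
formula and the PDB writer/parser.

## Single-pass clustering

Segments are processed in input order: each joins the cluster with the
nearest centroid if the distance is ≤ D_th (default 30°), else founds a new
cluster. The distance between two segments is the RMS of wrapped angular
differences over the 2L angles:

    D(a, b) = sqrt( (1/2L) Σ_k [Δ(φ_ak, φ_bk)² + Δ(ψ_ak, ψ_bk)²] ),

bounded by 180°. Centroids are per-angle circular means (atan2 of summed
sines and cosines), updated incrementally after every join; ties on the
nearest centroid break toward the lowest cluster id, making the procedure
fully deterministic for a fixed input order. The input order is therefore
part of reproducibility and is recorded in the CLI manifest. Medoids
(minimum summed distance to co-members, lowest index on ties) are computed
after clustering. The exact distance and centroid rules are isolated behind
two functions so alternative angular metrics can be swapped in.

The ≥ 80-member floor for profile building is applied *after* clustering:
small clusters are retained in cluster reports but produce no profiles,
since small samples give noisy propensities.

## Propensity profiles

For a cluster of member sequences, counts are raw occurrences per window
position; unknown residues ('X', nonstandard) are excluded from numerator
and denominator position by position. With p_i(j) the position frequency
and p(j) the composition over all segments, the profile is
pro_i(j) = p_i(j)/p(j). No weights and no pseudo-counts anywhere: a residue
unobserved at a position has propensity exactly 0, handled downstream only
by the logarithmic floor. Two identities are enforced by tests to 1e-9:
Σ_j p_i(j) = 1 and Σ_j p(j)·pro_i(j) = 1 per position.

PSI-BLAST ASCII PSSMs are ingested with their native column order
(ARNDCQEGHILKMFPSTWYV) re-mapped to the package's canonical alphabet
(ACDEFGHIKLMNPQRSTVWY) at the boundary; optional percentage columns are
read when present. The native profile TSV dialect round-trips both profile
types losslessly at 6 significant digits.

## Cross profile search

Column similarity is the Pearson correlation of two 20-vectors; a
zero-variance column yields similarity 0. Structure-profile columns enter
as ln pro_i(j) floored at −9.21 (= ln 10⁻⁴): correlation is invariant to
affine but not logarithmic transforms, and the compatibility score
establishes log space as the scoring space, so both column types are made
log-odds-like before comparison. A raw-propensity mode is kept in config.

Alignment is global with free terminal gaps, computed by affine-gap dynamic
programming (Gotoh states): any unaligned run at either end of either
profile costs 0, an internal gap of length k costs open + k·extend, and
simultaneous internal gaps in both profiles pay both penalties. The
default penalties (open 0.6, extend 0.06, in correlation units) make one
internal gap more expensive than the largest possible column gain (1.0)
minus a typical decoy column (≈ 0); they were fixed once on the planted
motif fixture and are exposed in `SearchConfig`. Traceback ties prefer
diagonal, then query-side gap, then target-side gap. Optimality is
verified against exhaustive enumeration of all monotone alignments on
small instances.

Raw alignment scores grow with target length, so library significance
removes a least-squares fit s ≈ a·ln(n) + b over the whole library and
standardises the residuals (population standard deviation) into Z-scores.
The exact length-correction recipe is a package choice isolated behind one
function; the Z ≥ 8 significance working point is the field's empirical
threshold for this scoring scheme. Libraries with fewer than 10 entries
get raw scores only (Z set to 0, nothing flagged significant), since a
regression on a handful of points is meaningless.

## Compatibility score and ΔS

S = Σ_{i=1..L} ln pro_i(j_i) for an L-symbol region threaded onto a
profile; gap symbols, unknown residues and zero-propensity residues all
contribute the fixed penalty −9.21. The constant is stored at its printed
2-decimal precision so that a gap contributes *exactly* −9.21 and S is
reproducible to the digit. The consensus (deduced) sequence is the
per-position propensity argmax (alphabetical on ties) and attains the
global maximum of S over gapless sequences, since the terms are
independent.

Family analysis takes a gapped alignment, a window of L alignment columns
(mapped 1:1 onto profile positions — the registration between alignment
columns and profile positions is the caller's choice, externalised as the
window specification) and a designated ancestral row. Members with no
amino acids in the window are excluded with reason "empty region"; an
ancestor empty in the window is an error, with an explicit parameter to
supply an alternate (next-root) ancestor instead. ΔS = S_member −
S_ancestor; the sign convention means negative values indicate drift away
from the motif.

## Evolutionary landscape

"PCA of sequences with Hamming dissimilarity" is implemented as classical
(Torgerson) multidimensional scaling — the standard identity when only
dissimilarities are given, equal to PCA of the implied one-hot encoding up
to scale. The Hamming distance counts differing symbols; gap vs residue
differs, gap vs gap does not. The Gram matrix −½·J·D∘²·J is
eigendecomposed; the top two eigenpairs (negative eigenvalues clipped)
give coordinates scaled by √λ, signs fixed so the first nonzero loading of
each axis is positive.

Surface interpolation defaults to barycentric-linear interpolation on the
Delaunay triangulation of the embedded points, with inverse-distance
weighting (power 2) outside the hull; a pure-IDW mode exists for
degenerate (e.g. two-point or collinear) configurations. Both are exact at
data nodes. The grid is 100×100 over the bounding box with 5% padding.
"Virtual" sequences for densifying a sparse map are seeded single/double
mutants of the data sequences.

## Synthetic study conditions

The generators define the default test-bed conditions:

- **Planted clusters**: k = 3 clusters of 50 members, angular noise
  σ = 3°. Centroids sit on a per-coordinate 360°/k grid (random base,
  random per-coordinate cluster permutation), so every pairwise centroid
  distance is exactly 360°/k = 120° at the default k — far above both the
  clustering threshold band (30–40°) and the intra-cluster spread. Larger
  pairwise separations are geometrically impossible: under the RMS
  wrapped-angle metric the best attainable minimum pairwise distance for
  three points is √(2/3)·180° ≈ 147°.
- **Sequence families**: 50 sequences mutated from a consensus at 10% per
  site (15% in the power analysis), converted to a PSSM with a single
  pseudo-count over a uniform background — a crude stand-in for
  PSI-BLAST's estimation machinery, confined to fixture generation and
  never used in propensity profiles.
- **Decoy libraries**: 200 PSSMs of length 30–120 with symmetric
  Dirichlet(0.5) column frequencies converted to log-odds, giving
  realistically sparse columns; one target embeds the family PSSM at a
  recorded offset.

What passing these conditions shows: the pipeline's machinery — distance
wrap-around, order-determinism, normalisation identities, DP optimality,
Z standardisation — is correct, and detection power at the Z ≥ 8 working
point holds under moderate divergence. What it does not show: performance
on real structure databases, where cluster shapes are anisotropic and
overlapping, PSSMs carry phylogenetic correlation the i.i.d. mutation
model lacks, and column score distributions are heavier-tailed than the
Dirichlet decoys.

## Problem sizes

Default verification sizes — 1,000 dihedral pairs for the round-trip, 100
random profiles for the normalisation identities, 20 seeds × 90 segments
for cluster recovery, 200 alignment instances for the DP oracle, 20 seeds
× 201-profile libraries for detection power — were chosen so the whole
suite exercises every guarantee at comfortable statistical margins while
remaining quick on a laptop.

## Known limitations

- Single-pass clustering is order-dependent by construction; results are
  reproducible only together with the recorded input order.
- The length-correction functional form (linear in ln n) is an assumption;
  heavy-tailed score distributions may need an EVD-based correction.
- Classical scaling of Hamming distances can produce negative eigenvalues
  (non-Euclidean configurations); they are clipped, which distorts large
  distances slightly when it happens.
- Profile–alignment registration for family scoring is not inferred; the
  caller must supply the window of alignment columns.
- Real-structure validation (e.g. superposing specific PDB segment pairs
  with `kabsch_rmsd`) requires the user to supply the coordinate files.
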