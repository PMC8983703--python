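# Methods

This note documents the models and procedures implemented in `zernsurf`,
the parameter choices that matter, and what the synthetic test bed does
and does not demonstrate.

## Surface construction

The solvent-excluded surface (SES) is approximated as a level set of a
distance field. Atoms are inflated by the probe radius (default 1.4 Å,
water); the union of inflated spheres is rasterized on a grid of spacing
`resolution` (default 0.6 Å); the Euclidean distance transform gives the
depth of each interior point below the solvent-accessible boundary; and
marching cubes extracts the iso-surface at depth equal to the probe
radius. Rolling the probe back off the accessible volume this way
reproduces the SES up to grid discretization: for a single atom the
result is its van der Waals sphere to within the grid resolution. Van der
Waals radii are a fixed Bondi-style table (C 1.70, N 1.55, O 1.52, S
1.80, P 1.80, default 1.70 Å). Degenerate (zero-area) triangles emitted
by marching cubes are dropped.

The triangulation is *not* intended to match any particular external
surface program triangle-for-triangle; the vertex/face counts carried
into the pair features are therefore internally consistent but not
comparable across surface generators. The descriptor consumes only the
coarse voxelization, which is insensitive to fine tessellation detail.

## Voxelization

The mesh is mapped onto an N³ cube (production default N = 200; the test
suite and the acceptance script use N = 48–64, which preserves every
qualitative property at a fraction of the cost). A voxel is 1 iff the
exact Euclidean distance from its center to the nearest surface triangle
is below 1.7 grid intervals; distances use a per-triangle candidate-box
pruning that is provably equivalent to the all-pairs test (and is checked
against an exhaustive oracle on small grids). Two numerical choices
stabilize the discretization:

* **Isotropic spacing from the mesh diameter.** The spacing is the mesh
  diameter (max pairwise vertex distance, via the convex hull) divided by
  the usable cube width, with a margin of cutoff + 1 voxels. Unlike a
  bounding-box-derived spacing, the diameter does not change when the
  object is rotated, so neither does the physical size of a voxel.
* **Canonical pose.** Before rasterization the atoms are rotated into
  their principal-axes frame (axes ordered by decreasing variance, signs
  chosen so each coordinate's skewness is non-negative, det +1). For a
  rotation-invariant descriptor this is a mathematical no-op, but it
  removes the lattice-alignment noise of rasterizing the same shape at
  different orientations: with it, the full pipeline is
  orientation-independent to machine precision. Axis-sign ambiguities at
  near-zero skewness only introduce reflections, which the invariants
  cannot see. For shapes with exactly degenerate principal axes the
  chosen frame is arbitrary within the degenerate subspace; the
  corresponding descriptor variation is bounded by the shape's own
  near-symmetry.

## Zernike expansion

The basis is Z_nl^m = R_nl(r) Y_l^m(θ, φ) with complex orthonormal
spherical harmonics (Condon–Shortley phase) and radial functions

    R_nl(r) = sqrt(2n + 3) · r^l · P_k^(0, l+1/2)(2r² − 1),  k = (n − l)/2,

which makes the basis orthonormal under the plain unit-ball inner
product. Moments are computed by direct summation over occupied voxel
centers, Ω_nl^m = (3/4π) Σ_j w_j conj(Z_nl^m(x_j)); only m ≥ 0 is
evaluated, with negative m filled by the conjugation symmetry
Ω_nl^{−m} = (−1)^m conj(Ω_nl^m), which holds exactly for real fields and
doubles as a correctness check. The invariants take the squared modulus
of each moment, F_nl = sqrt(Σ_m |Ω_nl^m|²) — the only reduction of the
(2l+1)-multiplet that is both real and rotation-invariant.

Normalization into the unit ball: occupied voxel centers are centered on
their centroid and scaled so the farthest point sits at radius 0.6,
keeping the shape strictly inside the ball where the basis is
orthonormal. The quadrature weights are normalized to unit total mass
(w_j = 1/K for K occupied voxels): the number of voxels straddling the
binary cutoff fluctuates with grid placement, and tying the overall
descriptor scale to a fixed total mass removes that noise from every
component. Because centering, scaling and mass are fixed conventions,
descriptors are comparable only between pipelines using the same
conventions; numeric identity with other implementations is not expected,
only equality of the structure *rankings* they induce.

The test suite verifies the moment computation against a fully
independent evaluation route (explicit Canterakis coefficient sums and
associated-Legendre harmonics with factorial normalization, versus Jacobi
recurrences and library harmonics in the implementation) to 1e−6, and the
basis orthonormality by Monte Carlo integration.

## Pair network

The same-fold network is a siamese architecture: one shared encoder
(121 → 250 → 200 → 150, rectified linear) embeds each descriptor; the
comparator input concatenates both raw descriptors, both concatenated
encodings (600 values each), four comparison metrics — Euclidean
distance, cosine distance, Manhattan distance (summed element-wise
absolute difference) and dot product (summed element-wise product) —
applied to the raw and to the encoded representations (8 scalars), and
the vertex/face count differences of the two surface meshes (2 scalars):
2·121 + 2·600 + 2·4 + 2 = 1,452 features. A hidden comparator layer of
128 rectified units feeds a sigmoid output, the same-fold probability.

Training: Adam, learning rate 0.005, binary cross-entropy, balanced
batches of 32 positive + 32 negative pairs drawn with replacement, 40
epochs by default with the best-validation-loss checkpoint retained
(10% of pairs held out). The implementation is plain numpy with
hand-derived gradients (verified against numerical differentiation);
given a seed, training is bit-deterministic. Element-wise metrics are
reduced to scalars by summation — the only reading consistent with the
1,452 feature count. The output layer is initialized near zero so the
first predictions sit at probability 0.5; at this learning rate a
conventionally scaled head starts overconfident and oscillates. The raw
network is not exactly symmetric in its two arguments, so the reported
score is the mean over both orderings.

Decision thresholds: 0.5 for full-atom descriptors, 0.6 for main-chain,
0.1 for the direct score 1/(1 + distance). Threshold provenance is the
operating point that maximizes F-measure on fold benchmarks; they are
defaults, not re-derived here.

## Confident domains

A residue is confident when pLDDT > 70.0 (strict). Qualifying runs are
maximal confident stretches of length strictly greater than 50; runs
separated by at most 5 non-confident residues are merged left-to-right to
a fixpoint, interveners included, with no re-check of the merged length
(each constituent already qualified). Profiles whose maximum value is
≤ 1.0 are treated as 0–1 scaled and multiplied by 100 on ingest, since
predicted-model PDB files conventionally store pLDDT on the 0–100 scale
in the B-factor column. All boundary readings (strict >50, inclusive ≤5)
are pinned by tests and checked against an independent scanner on 10⁴
random block profiles.

## Classes and folds

The expert cascades are first-match rules on (length, helix fraction,
sheet fraction): original — length < 50 aa → small; helix ≥ 60% → α;
sheet ≥ 35% and helix < 20% → β; else αβ; optimized — 55 aa, 55%, 25%
with the same 20% helix cap. The bagged ensemble trains 20 RBF-kernel
SVMs (gamma "scale", C = 1) on bootstrap samples of 5% of the data,
features standardized with training statistics (an addition for kernel
stability, recorded in the model), predicting by majority vote with ties
broken by summed class probability, then lexicographic class order.

Secondary-structure content is estimated from CA geometry alone: a
five-residue window is helical when the i→i+3 distance falls in
4.6–5.6 Å and i→i+4 in 5.5–6.9 Å (two consecutive windows required — a
single accidental match is common in coils); a residue is strand-like
when an i→i+2 window around it is extended (5.9–7.4 Å) and a
sequence-distant extended CA lies within 5.5 Å. This is deliberately
crude next to hydrogen-bond assigners; callers with DSSP-style
assignments can pass fractions directly. Fold assignment samples up to 10
exemplars per fold without replacement (seeded) and returns the fold of
maximum pair probability (maximum, not mean, over exemplars; both
aggregations are exposed).

## Synthetic test bed

The fixtures module generates every input the tests need: ideal
α-helices (1.5 Å rise, 100° twist — consecutive CA atoms 3.8 Å apart),
antiparallel β-sheets (3.3 Å per residue with a 0.6 Å pleat, strands
4.8 Å apart), compact self-avoiding CA random walks, piecewise-constant
pLDDT profiles whose jitter never crosses the 70 boundary, and
descriptor clusters standing in for fold families: centers drawn on the
non-negative part of a sphere of radius Δ = 1.0 in descriptor space,
members adding half-normal noise σ per component, plus per-fold surface
mesh counts.

The cluster defaults (10 folds × 20 members, Δ = 1.0, σ = 0.15) are
chosen to sit in the regime the pair network exists for: within-fold
variability large enough that the raw descriptor distance degrades to
roughly 0.85 held-out pair accuracy at its best threshold, while the
learned metric stays above 0.9. At much smaller σ both methods saturate;
at much larger σ the pair task is intrinsically hard. What the passing
tests show is that the architecture and training protocol recover fold
structure that raw descriptor distance blurs — on clusters with simple
elliptical noise. They do not show real-protein accuracy: genuine fold
families are not Gaussian clouds in descriptor space, surface meshes of
real structures are noisier than ideal-geometry fixtures, and no claim
is made that the synthetic accuracy figures transfer quantitatively.

## Problem sizes and numerical conventions

The test suite and acceptance script run the full pipeline at voxel
grids of N = 48–64 and surface resolution 0.6–0.8 Å with fixtures of
16–30 residues, and train the network on 3,000 pairs for 40 epochs —
sizes chosen so every property of interest is exercised at desk scale.
Production defaults (N = 200, order 20) are unchanged by any of this.
Ties in search rankings break by entry id; ties in fold assignment break
lexicographically; ensemble voting ties break by summed probability then
class order. All stochastic operations take explicit seeds, and
regeneration of any fixture is bit-identical.

## Known limitations

* The SES is a distance-transform approximation; deep crevices narrower
  than the rasterization resolution may close.
* Descriptors are convention-bound (centering, 0.6 scale, unit mass);
  compare only descriptors produced with identical settings.
* The CA-geometry secondary-structure assigner is a heuristic; its
  fractions drive the class rules faithfully but disagree with
  hydrogen-bond assigners on irregular elements.
* Multi-chain files are treated as one shape; chain splitting is the
  caller's responsibility.
* The pair network must be trained by the user (on descriptors of their
  own database); no pretrained weights ship with the package.
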