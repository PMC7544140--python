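# Methods

This note documents the models, estimators and numerical choices behind
`pitmorph`, what the synthetic generator does and does not emulate, and the
design decisions taken where the procedure was genuinely open.

## The synthetic tooth-pit model

A pit is a smooth elliptical depression in the z = 0 plane (right-handed
coordinates, millimetres, opening towards +z): a half-ellipsoid bowl

z(ρ, θ) = −D·√(1 − ρ²) + r·sin(mθ + φ)·4ρ²(1 − ρ²)

parameterised by radial fraction ρ ∈ [0, 1] and rim angle θ. The second
term is a smooth roughness field (amplitude `surface_roughness`, default
0.02 mm; integer wavenumber m ∈ {2..5} and phase drawn per pit) that
vanishes at both the rim and the centre, so the rim stays at z = 0 and the
bowl's depth extremum survives small perturbations. Pit length is uniform
over the published range 1.176–4.448 mm; width is uniform over
0.8382–3.5128 mm truncated at the drawn length (pits are longer than
wide, which keeps the orientation rule well defined). Maximum depth is
`depth_scale` × width × a log-normal factor with median 1 (shape 0.2).
`depth_scale` defaults to 0.25 for wolf and 0.45 for dog: the reported
finding is that dog pits are markedly deeper, but no depth values are
published, so the ratio is a package choice; the within-carnivore
morphological variance is likewise a free parameter rather than an
asserted value.

Ground-truth landmarks follow the scheme's definitions by brute force over
rim samples: LM1/LM2 terminate the maximum-length rim chord, LM1 being the
endpoint furthest from the perpendicular maximum-width axis (ties, which
occur for perfectly symmetric pits, break towards +x then +y); LM3/LM4
terminate the width axis with LM3 on the counter-clockwise side; LM5 is
the deepest interior point (grid search at 96×96 when the surface is
rough, exact otherwise). For the 17-landmark scheme, LM6–13 sit at 1/3 and
2/3 arc fractions between consecutive axis endpoints along the rim, and
LM14–17 are interior points at half the maximum depth along the four
half-axis directions — the intrinsically ambiguous Type III points.

Analyst error is an isotropic random unit vector times a log-normal
magnitude with median equal to the analyst's per-landmark noise scale and
shape parameter 0.6, reproducing the strong right skew of observed error
distributions. Default scales are the published per-landmark median
inter-analyst errors (LM1 0.282 … LM14 0.352 mm), multiplied by 1.3, 1.15
and 1.0 for analysts A1–A3; this reproduces the observed rank ordering of
landmark difficulty and analyst experience without asserting exact
magnitudes. Two consequences worth noting: (i) the *pairwise*
inter-analyst distances the raw-error tables summarise are larger than the
per-analyst displacement scales by a factor of roughly √2·(direction
geometry), so simulated raw-error medians are not expected to equal the
published table values; (ii) parameter recovery is therefore tested
against the generator truth (median displacement ≈ configured scale within
sampling error). For hybrid schemes the semilandmark points are computed
from the true rim anchors and then given a small digitisation noise
(median 0.08 mm), reflecting that computed points carry far less observer
judgement; sliding is exposed as its own operation and is not applied
inside study generation.

What the generator does **not** emulate: scanner noise and meshing
artefacts, bone-surface texture, partially preserved rims, analyst
systematic biases (noise is zero-median by construction), or correlations
between landmarks' errors. Passing tests therefore demonstrate the
*statistical machinery* — estimator correctness, invariances, orderings
induced by configured noise — not field performance on real scans.

## Superimposition

Ordinary Procrustes alignment uses the cross-covariance SVD with
determinant-sign correction, so reflections are never used (landmark sets
on bone are chiral). Full GPA centres all configurations, scales them to
unit centroid size, and iteratively rotates each to the running mean,
which is itself re-centred and renormalised each round; iteration stops
when the mean moves less than 1e-10 (max 100 iterations; the converged
flag records which). Partial GPA is the identical iteration with scaling
omitted everywhere; original centroid sizes are preserved exactly.
Procrustes distance is chordal (root-sum-of-squares after optimal
superimposition, unit-size in shape space); the geodesic variant is not
used. Zero-size configurations are rejected by name; collinear ones are
allowed.

The Pinocchio effect is checked as a property: perturbing one landmark of
one configuration in an otherwise identical ensemble produces strictly
positive apparent displacement at all other landmarks after full GPA,
while raw-coordinate analysis localises the error entirely. Comparing the
non-perturbed spread between shape space (unit size) and form space (mm)
is only meaningful when the base configuration has unit centroid size; the
test constructs it so.

## Robust statistics

MAD uses the numpy median convention (even-length samples: mean of the
central pair). NMAD multiplies by the literal constant 1.4826 rather than
a higher-precision Φ⁻¹(3/4), matching the convention as printed. BWMV
implements the biweight definition with weights aᵢ = 1 iff |Uᵢ| < 1,
Uᵢ = (xᵢ − m)/(9·MAD); samples with MAD = 0 return 0 (the estimator is
undefined when all mass sits at the median). Kruskal–Wallis, Shapiro–Wilk,
adjusted Fisher–Pearson skewness and Kendall's τ-b delegate to
scipy.stats; constant input yields skewness 0 and an error for τ.

## Repeatability

The repeatability measure is read as the ratio
RMⱼ = Σᵢ d²ᵢⱼ / Σᵢⱼ d²ᵢⱼ of analyst j's summed squared Procrustes
distances to the grand total (the common 1/(n − I) factor cancels), which
makes the analysts' RMs sum to one exactly and each lie in [0, 1].
Distances are taken to the mean configuration of all individuals;
per-analyst and per-carnivore references are exposed as options.
Unbalanced designs are refused rather than reweighted. All-zero distance
sets raise (the ratio is undefined).

## Morphospace statistics

PCA eigendecomposes the covariance of mean-centred flattened coordinates
via SVD; the dimensionality is the count of eigenvalues above 1e-12 of the
largest, component signs make each component's largest-magnitude loading
positive, and an ensemble with no variance beyond floating-point noise is
flagged degenerate. For MANOVA/CVA the scores are truncated to the
components covering 95% of variance, capped at n − g − 1 columns, to keep
within-group covariances non-singular. The MANOVA statistic is selected by
Shapiro–Wilk on the pooled first-two PC scores at α = 0.05
(Hotelling–Lawley trace if normal, Wilks' Λ otherwise), with analytic F
approximations for p. CVA is two-group: Mahalanobis D from the pooled
within-group covariance (pseudo-inverse for rank safety), "Procrustes D"
as the Euclidean distance between group mean score vectors (the scores
embed the aligned shapes isometrically), and permutation p-values with the
add-one estimator, so the smallest attainable p at 999 permutations is
1/1000.

UPGMA is a direct average-linkage implementation: merge heights are half
the average inter-cluster distance (so the tree is ultrametric and a
two-leaf tree at distance d has depth d/2), and ties break towards the
lowest leaf index. scipy's average linkage serves as an independent
cross-check in the tests, never as the implementation.

## Identifiability

The k-distance curve uses k = MinPts = 30, the number of pits digitised
per carnivore sample — one cluster should contain at least one sample's
worth of placements. The elbow is the point of maximum absolute deviation
of the [0, 1]-normalised curve from the diagonal (the kneedle criterion,
orientation-agnostic); straight lines raise a no-knee error so the caller
must supply ε explicitly. DBSCAN follows the standard core/border/noise
semantics (scikit-learn; the point itself counts towards MinPts, border
ties resolve by point order). Mean shift is a vectorised flat-kernel
implementation seeded from every point (convergence tolerance 1e-6, max
300 iterations); converged seeds within one bandwidth merge, densest mode
first, and singleton modes are reported as noise-equivalent points.
Bandwidth is the mean distance to the ⌈quantile·n⌉-th nearest neighbour
at quantile 0.05. Clustering pools all analysts and both carnivores, as
the evaluation design implies; a per-carnivore option exists via dataset
subsetting.

## Semilandmark patches and sliding

The patch is a bilinear grid over the quad framed by the four rim anchors
(cyclic order LM1, LM3, LM2, LM4), projected vertically onto the surface
and relaxed by alternately re-spacing columns and rows to equal arc length
(8 rounds, ending with a row pass), which drives the row spacing
coefficient of variation below 1%. Corners coincide with the anchors
bit-exactly. Sliding minimises thin-plate-spline bending energy against a
reference: the 3D TPS kernel U(r) = −r gives the bending-energy matrix as
the upper-left block of the inverted [[K, Q], [Qᵀ, 0]] system; each
non-corner point moves within its local tangent plane (tangents from
finite-difference surface gradients), the optimal tangent displacements
solve one linear system per round (3 rounds by default, standard
practice), and points are re-projected onto the surface after each step. A
backtracking line search guarantees the energy never increases despite the
re-projection. The reference is the current patch mean in study-level use;
mesh input is supported through brute-force nearest-triangle projection
(no spatial index required).

The patch-size sweep regenerates the same study (same seed, so the same
pits) under each grid size and flags the shape-space row maximising PC1–10
cumulative variance subject to MANOVA separation at α = 0.05.

## Problem sizes and determinism

The default study design is 30 pits per carnivore × 3 analysts
(180 configurations); unit tests use 6–15 pits per carnivore where the
property under test does not depend on the full size. All randomness flows
from a single integer seed through `numpy.random.default_rng`; equal seeds
give identical datasets, and pipeline reruns produce byte-identical
tables. Permutation tests default to 999 permutations; Monte-Carlo checks
in the tests use 100–200 seeded replicates.

## Known limitations

- The generator's pits are star-convex and smooth; heavily irregular or
  broken rims (common on real bone) are out of scope, as is any mesh/scan
  simulation.
- MANOVA p-values are analytic F approximations, not permutation-based;
  with 180 configurations and truncated scores they can underflow to 0 for
  strong contrasts.
- "Procrustes D" in CVA is computed in score space; with truncated scores
  it is a lower bound on the full-space mean-shape distance.
- The sliding criterion is bending energy to the reference; minimum
  Procrustes-distance sliding is not implemented.
- Raw-error comparability assumes all analysts digitise the same model in
  the same frame; configurations are not re-registered before raw error
  computation.
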