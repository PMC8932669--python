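# Methods

This note documents the models implemented in jawscape, the assumptions
behind them, the tunable parameters and their defaults, and what the
synthetic-data generator does and does not emulate. It states no empirical
result that the test suite or acceptance script does not itself compute.

## Outline geometry and elliptic Fourier analysis

Outlines are ordered closed polygons (first vertex not repeated),
counterclockwise, in arbitrary length units. Resampling places `n_points`
vertices at equal arc length along the polygonal boundary, preserving the
start vertex and orientation. Self-intersection is decided by the GEOS
simplicity test on the closed ring (adjacent edges sharing an endpoint do
not count).

The Fourier description follows the closed-polygon formulation of Kuhl &
Giardina (1982): per harmonic *n*, four coefficients (aₙ, bₙ, cₙ, dₙ) of
the chord-length-parameterized series, plus a DC offset. Normalization is
the standard first-ellipse rule — rotate the parameter to the first
harmonic's semi-major phase, rotate space to put that axis on +x, divide
by the semi-major length — yielding a₁ = 1, b₁ = c₁ = 0 exactly (snapped,
so normalization is exactly idempotent) and 4H − 3 free parameters. At
the default H = 12 the descriptor has 45 entries, flattened in the fixed
order (d₁, a₂, b₂, c₂, d₂, …, a₁₂, …, d₁₂).

Choices worth knowing:

* **Reflection is not removed** by normalization. Lateral jaw images have
  a consistent anatomical frame, so a separate `canonical_orientation`
  utility rotates the major axis onto x, puts the dorsal margin at +y
  (sign of the vertical skewness of boundary points) and the tapered
  anterior end at +x, before decomposition. Synthetic outlines are
  generated already in this frame.
* **Arc-length parameterization caveat.** The first harmonic of an
  eccentric ellipse traced by arc length is *not* the ellipse itself:
  for a 2:1 ellipse the first-harmonic axes are ≈ (1.83, 1.07), with the
  remainder in odd higher harmonics. The full series still converges to
  the exact shape; only the circle has an exact one-harmonic form. Tests
  assert this actual behaviour.
* The 180° phase ambiguity of the semi-major vertex is not canonicalized;
  rotation/scale invariance of a fixed outline (what the pipeline needs)
  is exact to 1e−6 and tested.

## Morphospace and the theoretical grid

The shape space is a centered PCA (full SVD) of the specimen-by-45
matrix; loadings are orthonormal columns, scores the specimen
coordinates. Projection is Lᵀ(x − mean); inversion with k axes is
mean + L₍:k₎s and is exact when all axes are used.

The theoretical grid spans the empirical [min, max] of PC1 and PC2, each
limit extended by `border_fraction` (default 0.2) times the **PC1**
empirical range — the PC1 range is the yardstick for both axes, giving a
uniform absolute margin. Defaults 23 × 21 = 483 nodes. Higher PCs are set
to exactly zero for theoretical shapes. Each node is inverse-transformed,
traced at 300 series points, screened for self-intersection (invalid =
geometrically impossible morphospace), and valid shapes are isotropically
rescaled about their area centroid to unit area so that performance
differences reflect shape only. Empirical specimens are not
area-standardized; their size was already removed by EFA normalization.

## Meshing

No external mesh generator is assumed. The mesher resamples the boundary
at the target edge length *h* = √(area / (√3/4 · target)), preserving
polygon corners (boundary turn > 25°; consecutive "corners" closer than
*h* along the boundary — a tightly curved smooth stretch such as a jaw
tip — are merged to the sharpest one), seeds the interior with a
hexagonal lattice kept ≥ 0.55 h from the boundary, Delaunay-triangulates
the point set, discards triangles whose centroids fall outside the
polygon, and runs four Laplacian smoothing passes on interior points.
The kept triangles must tile the (resampled) polygon exactly; an area
mismatch beyond 1e−8 (possible in deep concavities) triggers boundary
densification and retry. The element count converges to within ±15% of
the target by rescaling *h*; everything is deterministic. Minimum
interior angle is a soft floor (default 20°): a `MeshQualityWarning` is
emitted if an input's own geometry forces sharper elements. On the
synthetic jaw family, 2500- vs 3000-element meshes change RE and median
VMS by well under 2% (tested), matching the resolution-insensitivity the
analysis design assumes.

## Rotational efficiency

RE is the bite-point speed given one unit of rotational kinetic energy
about the joint: E = ½Iω² = 1 ⇒ ω = √(2/I), RE = L√(2/I), with L the
joint–bite distance and I = Σ mᵢrᵢ² summed over mesh elements (mᵢ =
density × area, rᵢ = centroid distance **to the joint**, the rotational
axis). Density defaults to 1; only relative values matter for ranking
(doubling density divides RE by √2, tested as a scaling law). The meshed
unit-area 4 × 0.25 rectangle reproduces the closed-form value
4·√(2/(L²/3 + W²/12)) ≈ 2.4483 within 0.5%.

## Plane-stress CST finite elements

Each jaw is a thin plate of uniform thickness (default 1) with
E = 2 × 10⁹ Pa and ν = 0.3. Constant-strain triangles give exact
constant-stress patch behaviour (tested to 1e−6 relative) and ~1%
accuracy against Euler–Bernoulli tip deflection for a slender cantilever
at ~2500 elements. Von Mises stress is √(σx² − σxσy + σy² + 3τxy²) per
element; the median over elements is the strength proxy, robust to the
singular stresses at point constraints.

Constraint scheme (configurable through `solve_cst`): the joint node is
fixed in x and y, the bite node in y only — fixing both nodes fully
would suppress the lever mechanics of the jaw. The unit muscle force is
applied at a boundary node. The reduced stiffness system is factorized
once per mesh (SuperLU) and reused across all force replicates.

## Randomized boundary conditions

The initial joint/bite are the posterior-/anterior-most boundary nodes
whose outward normal lies within 30° of +y ("near-vertical"); this
presumes the canonical anatomical frame and fails loudly otherwise. Per
Monte-Carlo replicate (all draws uniform; windows are hard bounds):

* **RE replicates:** joint and bite slide independently along the
  boundary by offsets within ±5% of the outline length (off-node
  positions allowed; no FEA is involved).
* **VMS replicates:** joint/bite stay fixed. The force node starts one
  third of the way along the **dorsal** joint→bite boundary path (the
  muscle-attachment side, identified as the candidate path with higher
  mean y), slides within the same ±5% window (renders to the nearest
  boundary node; draws colliding with a landmark are resampled, bounded),
  and the unit force direction is the outward node normal rotated by a
  uniform angle within ±45°. Outward is the default; pass-through
  configuration allows inward.

Per shape, means and 5th/95th empirical percentiles (linear
interpolation) of both metrics are recorded over n = 1000 replicates
(100 in the reduced pipeline). All randomness flows from one explicit
seed.

## Pareto ranking and the adaptive landscape

Goldberg ranking peels successive non-dominated fronts (dominance:
better-or-equal in all metrics and strictly better in ≥ 1; ties handled
by that rule alone, no epsilon). Run with (maximize RE, minimize VMS) it
gives R_O; with both reversed, R_S. Combined rank
R = (R_S − 1)/(R_O + R_S − 2) ∈ [0, 1]. **Degenerate case:** a point on
both first fronts (singleton sets, or corner points of a pure trade-off
set) makes the formula 0/0 and is assigned 0.5 — symmetric and bounded,
but note that in a set where *every* pair trades off, *every* point gets
0.5; inspect the raw front indices when this matters. Ranking uses
mean-over-replicates performance per grid node. The landscape is the
rank surface over valid nodes; interpolation is bilinear over the four
surrounding nodes and refuses queries outside the grid or touching an
invalid (self-intersecting) node with non-negligible weight.

## Phylogenetic comparative methods

Trees are rooted, with strictly positive branch lengths in Ma (Newick
I/O via dendropy); tree inference and dating are out of scope — the
dated tree is an input. Ancestral states under Brownian motion are the
ML point estimates, computed per trait as the weighted (1/branch length)
harmonic-mean linear system — identical to the GLS/weighted
squared-change solution; ML vs REML variance scaling does not affect the
point estimates. Ancestors are *projected* into the fitted shape space
with the existing loadings, never refitted. K_mult generalizes
Blomberg's K to multivariate data via the phylogenetic covariance matrix
C (shared root-to-MRCA path lengths): the ratio of non-phylogenetic to
phylogenetically corrected trait variation, scaled by its Brownian
expectation so BM data average 1 (calibration tested by simulation).
Significance permutes tip rows; p = (b + 1)/(n + 1) with
b = #{K_perm ≥ K_obs}, n = 9999 by default.

## Time binning, disparity, trends

Default bins: one merged late Silurian bin (427.4–419.2 Ma,
Ludlow + Pridoli) plus the seven Devonian stages, ICS 2020 boundaries,
stored in code and overridable. Membership is by closed-interval overlap
of the taxon range with the bin, then ranged through: a taxon occupies
every bin between its first and last occupied bin. Disparity per bin on
the 45-trait harmonic data: sum of sample variances (n − 1 denominator)
and mean pairwise Euclidean distance. Bootstrap: resample taxa with
replacement, 10,000 replicates, report the bootstrap mean and empirical
2.5/97.5 percentiles (CI type is a choice; percentile was selected for
its distribution-freeness). Mean bin optimality bootstraps the mean of
landscape ranks interpolated at member taxa's PC scores. Trends are
Spearman rank correlations of each per-bin series against time order;
the disparity–optimality relation is a Pearson correlation. Single-taxon
bins get NaN disparity rather than silently dropping.

## Synthetic data: what it emulates, what it does not

`generate_jaw_outline` builds a silhouette from a superellipse-profile
ventral margin (exponent 2.5, blunt jaw-like ends) under a parabolic
dorsal margin, with four knobs: length/depth ratio (the dominant
long-shallow ↔ short-deep axis), dorsal curvature (+ = concave dip,
− = convex bow; the second axis), anterior taper, and a small smooth
roughness term (three low-order sinusoids along vertex normals, faded
near the high-curvature tips where any normal displacement would fold
the boundary). The documented valid box — ratio ∈ [2, 8], curvature ∈
[−0.45, 0.45], taper ∈ [0, 0.7], roughness ∈ [0, 0.05] — guarantees a
simple outline (property-tested across the box); outside it generation
refuses. Taxon sets draw ratio ~ U(2.5, 6), curvature ~ N(0, 0.15)
clipped to ±0.4, taper ~ U(0.1, 0.5), roughness 0.005 — chosen once as
a realistic spread that reproduces the qualitative PCA structure (a
dominant ratio axis, a secondary curvature axis); clade labels follow
the 57:48:8:8 four-clade proportions of the empirical sample; ranges
place a uniform midpoint in the binned interval with exponential
(mean 8 Ma, capped 25 Ma) durations. Trees are Yule-style random
bipartitions with recursive uniform node ages (ultrametric, all branch
lengths positive); BM traits add independent Gaussian increments with
covariance rate × branch length and return the true internal states for
recovery tests.

A green synthetic test therefore establishes that the machinery is
correct and internally consistent — not that any empirical result holds:
real jaw samples have preservation bias, non-random clade sampling,
fossil (non-ultrametric) tip ages, 3D shape variation collapsed into 2D,
and shape distributions no four-knob generator reproduces. Headline
empirical quantities (variance fractions, K_mult values, named-taxon
optimalities) depend on the unreleased fossil dataset and are out of
scope here.

## Numerical choices and degenerate inputs

* Tolerances: equal-arc resampling to 1e−6 relative; normalization
  snaps a₁, b₁, c₁ exactly; PCA round trips to 1e−8; mesh area
  conservation to 1e−8 relative; unit-area standardization to 1e−9.
* Zero-length outlines, constant coefficient matrices, non-PSD rate
  matrices, constant tip data, zero-area polygons, missing tip data and
  singular stiffness systems all raise explicit errors rather than
  propagating NaNs.
* Degenerate Monte-Carlo windows (width 0) reproduce the deterministic
  base configuration exactly; n = 1 replicates collapse mean and both
  percentiles to the same value.

## Known limitations

* 2D plane stress only; no material heterogeneity, contact or muscle
  architecture; thickness uniform.
* The mesher's 20° minimum angle is best-effort, not guaranteed, for
  shapes whose own corners are sharper — extreme border shapes of the
  theoretical grid can mesh with sliver elements (warned, not fatal).
* Bilinear landscape interpolation is undefined inside invalid cells;
  taxa projecting there are reported, not imputed.
* ASR assumes trait independence (per-trait BM), matching the standard
  treatment of coordinate data; correlated-trait BM is not implemented.
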