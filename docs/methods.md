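# Methods

## Volume-conductor model and discretization

The head is a voxel volume with per-voxel isotropic conductivity σ
(S/m); air is exactly σ = 0. Under the quasi-static approximation the
scalar potential obeys ∇·(σ∇φ) = −∇·J. Potentials live on the node
lattice at voxel corners (a grid of shape `shape + 1`). Every lattice
edge of length h carries a conductance

    S = σ̄ · h,        σ̄ = mean conductivity of the ≤4 voxels sharing the edge,

with air (and out-of-grid) voxels contributing zero to the mean but
counted in its denominator; for cubic voxels the h² cross-section over
the h length leaves a single factor of h. Kirchhoff's current law at
node 0 with neighbors n gives the row Σₙ Sₙφₙ − (Σₙ Sₙ)φ₀ = −I₀, a
symmetric graph Laplacian over head nodes (nodes with at least one
conductive incident edge). Sources are equivalent injected nodal
currents: a one-edge dipole is +I/−I on two adjacent nodes; a lead-field
injection is +I at an electrode node and −I at the ground node. Air is a
pure Neumann boundary realized by the zero-conductance edges; the
constant nullspace is removed by pinning one reference node (the ground
electrode) to 0 V. A disconnected head mask is rejected, since the
potential between components would be undefined.

Units are SI throughout: mm grid spacing converted to meters inside edge
conductances and field gradients, currents in amperes, potentials in
volts, current density in A/m².

## Solvers

- **SOR** (`method="sor"`): lexicographic sweeps with relaxation factor
  ω (default 1.9), residual checked every other sweep. Convergence is
  declared at relative residual ‖b − Aφ‖/‖b‖ < tol (default 10⁻⁶).
- **Geometric multigrid** (`method="mg"`): V-cycles with forward-SOR
  pre-smoothing and backward-SOR post-smoothing (2+2 sweeps, smoother
  ω = 1.2 — relaxation near 2 accelerates standalone SOR but is a poor
  smoother), factor-2 coarsening of the conductivity volume by 2×2×2
  block averaging (air-padded to even dimensions), coarse operators
  rediscretized from the coarse conductivities, trilinear prolongation
  with its adjoint as restriction, and a cached sparse LU at the
  coarsest level. The hierarchy depth is configurable; by default the
  grid coarsens until some axis has fewer than 8 voxels.
- **Preconditioned CG** (`method="mgcg"`, the default for lead-field
  and Monte-Carlo workloads): conjugate gradients preconditioned by one
  symmetric V-cycle. Measured on the 2 mm five-shell sphere, stationary
  V-cycles converge in 6 (homogeneous) to ~180 (fully segmented)
  iterations — strong conductivity jumps (skull 0.02 vs CSF 2.0 S/m)
  degrade coarse-grid corrections built from averaged conductivities —
  while mgcg needs 6–14 iterations on every model variant at well under
  a second per solve. Using the multigrid as a preconditioner rather
  than a standalone iteration is therefore the package's workhorse
  configuration.
- **Direct** (`method="direct"`): sparse LU of the pinned system, used
  for small grids and as the oracle in tests.

A note on tolerances: the convergence criterion bounds the *residual*,
not the solution error; the gap is the system's conditioning. On a 16³
shelled phantom a 10⁻⁶ residual leaves up to ~4·10⁻⁴ relative solution
error. Tests that compare solver routes therefore tighten the residual
(10⁻⁸–10⁻⁹) so they measure algorithmic agreement rather than
truncation; production solves keep 10⁻⁶, which is ample for
localization (see limitations).

## Lead field by reciprocity

The lead-field matrix L (M electrodes × 3N gray-voxel components, x/y/z
interleaved voxel-major) is built with one forward solve per non-ground
electrode: inject I between electrode m and ground, and set row m to the
induced electric field per gray voxel divided by I. The field component
for voxel (i,j,k) along x is sampled on the voxel's *base edge*,
E = (φ(i,j,k) − φ(i+1,j,k))/h — the same lattice edge a one-edge test
dipole at that voxel occupies. This makes the discrete reciprocity
identity exact up to solver tolerance: the dipole-induced referenced
potential at electrode m equals −I_d·h·L[m, col]. Consequently,
noise-free potentials from a matched model are exactly a scaled column
of L, and matching pursuit recovers the true voxel (correlation 1).
The ground row is identically zero; L is stored dense (M is small) with
entries E/I, column norms computed lazily at query time; an HDF5
container with montage/grid metadata serializes it.

The sign of the reciprocity identity depends on the injection-direction
convention and is irrelevant to localization, which by default
correlates with |corrcoef|: a polarity-reversed dipole produces the
negated scalp pattern, which a signed argmax would miss while carrying
no location information. The signed mode is available for completeness.

## Matching pursuit

corrcoef(i) = φ·Lᵢ/(‖φ‖‖Lᵢ‖) for all 3N columns; the argmax (of the
absolute value by default) is the estimated source, converted to
(voxel, axis) and the voxel-center location in mm. Zero-norm columns
(shielded voxels at coarse resolution) get correlation 0; ties beyond
10⁻¹² resolve to the lowest column index and are logged. For k sources
the greedy pursuit subtracts the least-squares projection onto all
selected columns before re-correlating, so residual norms are
nonincreasing; it stops early at machine-zero residual. No 3N×3N object
is ever formed — time and memory stay O(N) per query. The
current-density map of an estimate is produced by re-solving the
forward problem with a dipole at the estimated location (the pursuit
coefficient itself does not satisfy Kirchhoff's law) and taking
j = −σ∇φ with face-averaged central differences at voxel centers.

## Phantoms

`make_layered_sphere` builds concentric shells labeled outermost-in
(default: scalp 85, skull 78, CSF 72, gray 70, white 55 mm outer radii —
a thin high-σ CSF shell between resistive skull and brain, the feature
that dominates localization accuracy in real heads). A voxel takes the
innermost shell containing its center; shells thinner than one voxel are
rejected by name. Conductivities come from a 14-tissue low-frequency
table (gray 0.0275, CSF 2.0, cortical bone 0.02, skin 0.1 S/m, …).
Four variants share one grid and head mask:

- *anatomical analog*: per-tissue table values;
- *homogeneous*: gray-matter conductivity everywhere;
- *CSF-insert*: homogeneous plus the true CSF shell;
- *segmentation-free*: the segmented field smoothed inside the head by a
  normalized masked Gaussian (default FWHM 2 mm), emulating conductivity
  volumes estimated directly from images, whose tissue transitions are
  gradual rather than abrupt. Masked normalization keeps air out of the
  head, preserves the σ mass up to the mask correction, clips to the
  input range, and converges to the segmented input as FWHM → 0.

What the sphere does *not* emulate: cortical folding (gyri/sulci), the
11 further tissue classes, anisotropic white matter, and realistic
scalp geometry. Passing tests therefore demonstrate the correctness of
the discrete machinery and the *direction* of the model effects
(noise monotonicity, montage density, mismatch penalty), not the
paper-grade millimeter error levels of a subject-specific head.

## Montages

Electrode directions are generated from the standard proportional
scheme on the unit sphere (vertex on +z, nasion +y): midline sites at
10% steps of the nasion–inion arc, the 10%-ring at θ = 72° with 5% or
10% azimuth steps, interior rows by great-circle interpolation between
ring and midline sites, and for the 10-10 set the reference-plane ring
(Nz, Iz, F9/10…P9/10) plus the earlobes A1/A2 — 75 sites total; the
classic 10-20 set has 21 including A1/A2. The exact 75-label roster is a
package choice (the proportional standard admits several equal-count
rosters); counts, symmetry and relative density are what the
experiments depend on. Each direction is snapped to the outer-surface
lattice node (touching both head and air voxels) of maximal angular
agreement, ties broken outward; colliding electrodes at coarse spacing
raise an error advising a finer grid. The ground electrode defaults to
the first label in canonical order and is configurable; all referencing
subtracts the ground potential, and matching-pursuit results are
invariant to a common re-reference of φ and L.

## Evaluation harness

Each trial places a one-edge dipole at a uniformly random gray voxel
(sampled without replacement when trials ≤ N) with a random axis and
random sign, solves the forward problem once, and reuses that field for
every (lead field, SNR) cell: Gaussian white noise is added per
non-ground electrode with variance P_signal·10^(−SNR/10), where
P_signal is the mean squared ground-referenced potential over non-ground
electrodes (the ground stays exactly 0; SNR = ∞ is the identity). The
localization error is the Euclidean distance between true and estimated
voxel centers; source depth is the distance to the head centroid (the
sphere center — the analog of the point below the vertex and ear
electrodes). Reports are per-trial DataFrames; summaries give mean ± SD,
max, the fraction below 10 mm, 0.5 mm-binned cumulative distributions,
Pearson depth–error correlations, and pooled two-sample two-tailed
t-tests between models with errors pooled across all SNR levels
(Welch's variant by flag; two constant equal samples define p = 1).
Everything is reproducible bit-for-bit from (seed, config); noise draws
consume one generator in a fixed loop order.

Default experiment sizes: the shipped study conditions are the 2 mm
sphere with 50-trial noise-free and 100-trial noise-sweep designs
(historically 500-trial runs at 0.5 mm are supported by the same code
path; `n_trials` and `spacing` are parameters). The examples and unit
tests use a 4 mm / 44 mm mini sphere that keeps all five shells.

## Numerical choices and edge cases

- Arithmetic (not harmonic) edge averaging: the conventional SPFD
  choice; flagged as open in the design notes.
- Pinning vs. deflation for the Neumann nullspace: pinning the ground
  node keeps the system SPD and makes every solve ground-referenced for
  free.
- Coarse-level pins move to the nearest coarse head node when the fine
  pin has no coarse image.
- `assemble_system` exposes the raw singular Laplacian (row sums 0) for
  inspection and testing; solvers work on the pinned reduction.
- Degenerate inputs: zero RHS returns the zero field without iterating;
  zero-signal noise injection and zero-norm observations raise; the
  CSF-insert of a CSF-free label volume warns and degrades to the
  homogeneous model.
- Tie-breaking, zero-norm columns, and solver failures (max iterations
  with residual history attached) are all explicit code paths.

## Known limitations

- Isotropic conductivity only; no tensors, no frequency dependence.
- Localization error is quantized to the voxel grid (estimates are
  voxel centers), so sub-voxel accuracy statements are meaningless at
  desk scale.
- Deep sources produce nearly collinear lead-field columns; at residual
  10⁻⁶ an occasional matched noise-free trial lands on a neighboring
  voxel (≈1–2% of trials at 2 mm). Tightening the residual removes
  these at proportional cost.
- The stationary V-cycle degrades on strongly segmented volumes (use
  `mgcg`); Galerkin coarse operators would be the next improvement.
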