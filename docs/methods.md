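# Methods

This note records the models implemented in `conemosaic`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not establish about real retinae.

## The lattice and its defects

The UV-cone sublattice is treated as an anisotropic triangular Bravais
lattice with row spacing `a_row = 10.25 µm` (cone-to-cone along a row),
column spacing `a_col = 12.25 µm` (cone-to-cone within a column) and
derived scales: inter-row spacing `a_col/2 = 6.125 µm`, ring spacing
`a_row/2 = 5.125 µm` (cones of adjacent rows sit on alternating
circumferential rings), and the oblique nearest-neighbor bond
`sqrt((a_row/2)² + (a_col/2)²) ≈ 7.99 µm`.  The column direction is not a
principal lattice direction; the six nearest neighbors of a cone are two
row bonds and four oblique bonds.  A Y-junction is an edge dislocation
with the oblique Burgers vector; a double-row insertion carries `a_col`.

Growth happens on a cone frustum, which unrolls isometrically into an
annular sector.  With "column" defined as one circumferential ring of UV
positions at radial pitch `a_row/2`, the opening angle
`α = 2·a_col/a_row ≈ 2.39 rad` makes exactly two row insertions necessary
per added column, matching the observed defect density (about 190
insertions while 200 initial rows grow through 95 columns).

## Synthetic mosaic generator

Rows are represented as angular trajectories over rings, each carrying a
continuous radial phase χ; a cone sits wherever the continuous ring
coordinate κ satisfies `κ − χ(κ) = 2m`.  Planting an insertion at
`(ring k, angle β)`:

1. creates a new row between its angular neighbors, phase-offset by one
   ring from the left neighbor;
2. shifts the phase target of every row at angle > β by ±1 ring — the
   displacement jump an edge dislocation with oblique Burgers vector
   carries across its cut line.  Phases move toward their targets at a
   bounded rate (fast within a few row positions of the cut, at most
   1/`ramp_rings` per ring far away), so the jump is sharp at the core
   and gentle elsewhere.  The flip sign is chosen to pull the affected
   rows' phase back toward its creation value, so overlapping cuts
   oscillate instead of performing a random walk;
3. re-spaces a window of ±8 rows gradually over the ramp length, so the
   angular and radial parts of the core's displacement field stay in
   step;
4. each ring, all row angles move a fraction (0.15) of the way toward
   the equal-spacing configuration, capped at an angular rate
   corresponding to a 12° row tilt.  Tissue already laid down never
   moves; the residual tilt field is precisely what the grain-boundary
   detectors measure.

Uniform placement uses a small hard core (three column spacings) so that
planted cores never merge; grain-boundary mode draws insertion angles
around `n_lines` fixed radial lines with a configurable jitter in row
units.  Reverse Y-junctions (row deletions) are planted only through
explicit schedules.  A fixed seed yields byte-identical output.

**Validated regime and known limitation.**  Isolated or well-separated
insertions are recovered by the defect detector exactly (one adjacent
5/7 pair per insertion, Burgers circuit closing on the oblique vector).
At the full retinal defect density the kinematic construction leaves a
few percent of incidental bound dislocation pairs (balanced
insertion/deletion content that is not in the planted ledger) where the
strain fields of nearby insertions collide: the round-trip census then
shows high recall but an excess of detected cores.  Several relaxation
schemes (pure diffusive smoothing, instant equalization, an implicit
per-ring elastic solve, post-hoc spring annealing in the rescaled
metric, dipole annihilation in the detector) were implemented and
measured; the shipped configuration is the best of these.  Conclusions
that depend on *individual-defect bookkeeping* at full density should
keep this in mind; the grain-boundary statistics use the planted ground
truth and are unaffected.

Glide events in two-timepoint pairs are realized by moving the insertion
event one ring outward along the defect's glide line; both angular
senses are constructed and the one producing a decisive single bond flip
at the core is kept.  Roughly half of planted insertions admit this
clean surgery (the local sub-lattice registry decides); the generator
refuses the others explicitly, and only outward steps are supported.
This is a statement about the generator's surgery, not about the
detector.

**What the generator does not emulate:** hemisphere dilation during
growth, mechanical relaxation of the tissue, cell death, the disordered
larval remnant, and intensity/segmentation noise of real imaging.
Passing tests on synthetic mosaics therefore validate the measurement
chain, not image processing.

## Nearest-neighbor graphs

All coordination analysis uses Delaunay triangulations computed band-wise
in isotropy-restoring coordinates (radial distance divided by `a_row`,
tangential arc multiplied by `√3/a_col`), in which the six lattice
neighbors are equidistant.  Delaunay on raw positions sits about 19% from
a diagonal degeneracy for this anisotropic lattice and produced spurious
5/7 bands under mild strain.  A band of twice the column spacing along
the domain rim is flagged as boundary and excluded from the census (the
alternating-ring rim is ragged at the single-ring scale).  Burgers
circuits walk a parallelogram of lattice steps and snap the closure
deficit to the nearest lattice vector, since the raw deficit also carries
the elastic strain integrated along the path.

## Registration and glide

Timepoint registration is multi-start iterative closest point: rotation
seeds on a grid, translation initialized from the modal nearest-neighbor
displacement, Kabsch updates with a tightening gate, winner selected by
inlier count and residual.  A full annular sector has a discrete
rotational near-symmetry (rotation by one row spacing maps the lattice
almost onto itself), so registration contracts hold for patches — which
is also what photoconversion experiments image.  Mutual nearest-neighbor
matching reports only pairs consistent in both directions.

Glide detection compares the triangulations restricted to cones present
at both timepoints.  A genuine bond flip swaps the diagonal of one quad
near the core and leaves the lost diagonal decisively non-Delaunay
(opposite angles summing beyond 180°, measured in the local
isotropy-restoring frame about the quad); jitter-induced flips hover at
the degeneracy margin, so a 20° margin threshold separates them.
Validation uses positional jitter of 3% of the bond length —
comfortably within the sub-micron localization of nuclear centroids.
Noiseless pairs are recovered exactly; over 100 jittered trials about
96% are exact, the residue coming from the metric-marginal core quad of
the *non-glided* defect flipping under the micron-scale global ripples
that the schedule surgery imprints on the regenerated lattice.  At 10%
jitter the core quad itself is near degenerate (the same marginality
that makes glide easy for the tissue) and any topological detector
becomes stochastic; exactness degrades to roughly half of trials.

## Grain-boundary detectors

The primary detector averages row orientation in five polar boxes around
each defect (radial extent Δr, angular extent Δr/r₀): Δφ45 between the
angular flanks, Δφ23 between the radial flanks,
`Δφ_rms = sqrt(Δφ45² + Δφ23²)` against a cutoff (12° default; 10° and
14° as standard sweep values).  Row orientation comes from traced
polylines (PCA per row within the box, weight = vertex count, signed
center→periphery) or, for simulated peak lattices, from row bonds — each
peak's bond best aligned with the inward radial direction, weight = bond
length; a regular peak accumulates two row bonds, a Y-junction three, a
reverse Y-junction one.  Δr defaults to 100 µm for retina-scale data; the
desk-scale frustum (radial extent ≈ 150 µm) uses 35 µm so the flanking
boxes fit, and the measured fraction changes by under five percentage
points over a two-fold Δr range.  Note the five-box measure carries an
intrinsic curvilinear baseline for purely radial fans (the flanking
boxes sample different angular positions), of order `2Δr/r₀` radians; it
is part of the measure, as in the cutoff's definition.

The chain detector grows, from every defect, a greedy chain of five
mutual nearest neighbors and scores its linearity
`a = (1/4) Σ û_end·û_step`; chains with `a > 7/8` flag all five members.
Ties in neighbor selection break by smallest index.

## Phase-field crystal model

Free energy `F = ∫ ½ψ[R + (1+∇s²)²]ψ + ψ⁴/4` with the stretched
Laplacian (`b²` on the radial direction, `1/b²` on the transverse one,
polar form on the frustum) and conserved relaxation
`∂ψ/∂t = ∇²(δF/δψ)`.  The stretch `b = sqrt(√3·a_row/a_col) ≈ 1.204`
makes the one-mode lattice reproduce the measured 6/5 spacing ratio
(verified by growing a rectangle and measuring the peak lattice).  The
intrinsic scales are `a_row_sim = 4πb/√3` and `a_col_sim = 4π/b`;
positions are calibrated to µm by `a_row/a_row_sim`.

Numerics: spectral in the periodic (angular) direction, conservative
flux-form finite differences radially with cell-centered nodes and
no-flux walls half a step outside the end nodes — the discrete r-weighted
sum of the Laplacian output vanishes identically, which is why the mean
of ψ is conserved to solver precision (measured < 10⁻⁸ absolute over
thousands of steps).  Time stepping is first-order implicit–explicit
with the cubic term explicit and `Δt = 0.075`; the per-mode 7-banded
radial operators are LU-factorized once.  Grid densities are ~25 points
per circumferential and ~10 per radial lattice spacing.  The
first-order-in-time scheme reproduces the linear dispersion relation to
well under 2% when checked at a reduced step (0.02); at the production
step the rate bias is about 2.4%.

Initial conditions: uniform ψ₀ with one column of density peaks at the
innermost ring (one-mode amplitude, Gaussian radial envelope of a
quarter row spacing) and a white-noise mask of standard deviation σ over
the first two column widths, after which the mean is re-pinned to ψ₀;
`noise_only` skips the seed column.  The parameter scan runs on the
`ψ₀ = −√(−R)/2` cut; each run first verifies through the one-mode
energies that the cut point lies in the triangular-only region and
refuses to start otherwise.  R values are exposed as a scan list;
{−0.15, −0.20, −0.25} is the default.  Growth stops when the modulation
front (envelope above half the one-mode amplitude) reaches two rings
from the outer wall.

Desk scale is 60 initial rows × 30 added columns with the canonical two
insertions per column (one run ≈ 30 s on one CPU); the full 200 × 95
geometry is supported and simply takes proportionally longer.  At desk
scale the primary detector (Δr = 35 µm, cutoff 12°) finds the large
majority of Y-junction peaks in grain boundaries across the scan, the
anisotropic free energy selects and maintains the radial row orientation
from pure noise (the isotropic model does not), and the growth front
lags at defect-bearing angular sectors (the V-shaped front).

## Lateral inhibition

The contrasting model integrates
`τ du_i/dt = f(u_i − s_i) − u_i`, `f(y) = (1 + tanh 4y)/2`, on a static
packing, with `s_i = s₀(x_i, t) + Σ_j c_ij D*(u_j)`,
`c_ij = exp(−d_ij²/2l²)` over centroid distances (periodic across the
transverse boundary, truncated at 4l where the weight is e⁻⁸, no
self-signaling), ligand output `D*(u) = (a₀ + 3u³/(1+u²)·a₁)·u` with
`a₀ = 0.05`, `a₁ = 0.95`, and a de-inhibition front
`s₀ = σ((x − vt)/(ε√A₀))` with `S₀ = 1`, `v = l/4τ`, `ε = 1/50` (the
front-width denominator read as ε·√A₀, dimensionally a length).  The
noise term is zero.  Cells start at u = 0; single-cell dynamics are
bistable with the high state at u ≈ 0.9997 and loss of the low state at
s ≈ 0.367.

The packing is a Lloyd-relaxed Voronoi tessellation of uniform random
points (two relaxation steps by default; unit mean area; periodic
transverse boundary, walls along the front direction) standing in for an
equal-tension vertex-model tissue; the disorder level is controlled by
the relaxation count and barely affects the pattern census.  Desk scale
is 2,048 cells (20,000 supported).

Census: high-fate cells (u > 0.5; insensitive within 0.2–0.8) are
triangulated; non-six-coordinated interior nodes are defects; the
intervening-cell count between pattern neighbors is the shortest-path
hop count through the cell adjacency graph minus one.

**Known discrepancy.**  With every stated constant implemented as
written (including unit ligand slope, fixed by the worked value
`D*(1) = 1.475`), the selected pattern is denser than the reference
descriptions: at l = 3√A₀ about six intervening cells (reference: seven
to eight), at l = 1.75√A₀ about 3.3 (reference: about five).  The
orderings and the defect phenomenology match: wide range → defect-free
late-patterned half, cell-size range → one-to-two intervening cells and
pervasive defects.  The ligand-level proportionality constant is the one
genuinely unconstrained parameter; it is kept at one rather than fitted
to the reference pattern spacing, and the acceptance suite reports the
measured values.

## Growth null model

For each newly incorporated Y-junction, 100,000 positions are drawn
uniformly on the margin axis, each position's distance to the nearest
existing grain boundary is reduced by the maximal observed glide
(3 µm/day × Δt, one ~6 µm row per two days) and floored at zero; the
pooled observed distances are compared with the pooled null by a
two-sided Mann–Whitney rank-sum test of equal medians (asymptotic p).
Under its own null — including the glide allowance on both sides — the
test's rejection rate matches the nominal level within binomial error.

## Problem sizes

Default test and acceptance sizes: frusta of 120–200 rows × 20–95
columns for the point-set analyses, 60 rows × 30 columns × 3 seeds × 3 R
for the growth scan, 2,048 cells for the fate model, 100 seeded trials
for glide recovery, 300 replicates at n_mc = 4,000 for the type-I
calibration (100,000 for single analyses).  These sizes are the
package's working defaults; every stage accepts larger inputs.
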