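# Methods

This note records the models behind each stage, the defaults and why, the
numerical choices, and the known limitations. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## Rate estimation and preprocessing

Spike (or calcium-event) times become continuous rates by summing unit-area
Gaussian kernels (width `sigma_smooth`, default 60 ms for the topology
path; the clustering path uses a wide 0.3 s kernel sampled every 30 ms).
Kernels are truncated at ±5 sigma (< 1e-6 mass lost). The unit-area
normalization puts rates in events/s; the downstream square root and
correlation steps are normalization-invariant, so this choice is cosmetic.

Rates are square-rooted (variance stabilization for Poisson-like counts),
speed-filtered (default minimum 5 cm/s; silent population vectors can also
be dropped for event data), then z-scored per neuron over the retained
samples and PCA-whitened to `d` components (default 6). Z-scoring follows
speed filtering; the opposite order is a documented switch one could add,
but filtering first means the normalization reflects only the analyzed
samples. Whitening uses the full SVD and rescales components to unit
population variance, so the retained covariance is the identity to 1e-8.

## Ensemble detection

Time-lagged cross-correlations `c_ij(tau)` over lags 0..tau_max (default
3 s at the 30 ms clustering step) are collapsed to
`C_ij = min/max over both orderings jointly` (the min and max are taken
over the union of `c_ij` and `c_ji` across the lag window; a flat
correlogram gives 1, i.e. no evidence of coupling; all-zero pairs are
defined as 1 and logged). Neuron features are rows of `C` squared
elementwise with the degenerate self-entries excluded; the pairwise
distance is one minus the Pearson correlation of features, clustered by
average-linkage agglomeration cut at `rho` (a per-dataset quantity, passed
in correlation-distance units), and clusters below 19 neurons are dropped
as too small to support a torus readout.

## Downsampling

Radial pass: greedy maximin. Start from the point with maximal summed
absolute coordinates, discard everything within `eps` of a landmark, and
repeatedly add the survivor with the largest minimum distance to the
landmark set. All retained pairwise distances are >= eps.

Fuzzy pass: per-point kernel widths `sigma_x` solve
`sum_{y in N_x} exp(-d(x, y)/sigma_x) = log2(kappa)` over the kappa nearest
neighbors (bisection, 1e-8 relative tolerance; duplicate-saturated points
take the sigma -> 0 limit and are logged). Directed memberships are
supported on the kappa-NN graph — `mu_x(y) = 0` for y outside `N_x` — and
symmetrized by the probabilistic sum `mu_x + mu_y - mu_x mu_y`. The support
restriction is what makes the selection density-seeking: an isolated
outlier belongs to no one's neighborhood, so its summed membership is
minimal and it is never selected, whereas with full support its adaptive
sigma would blow up and it would paradoxically win the first pick. The
greedy selection maximizes the summed membership to the residual cloud,
maintained incrementally (subtract the chosen point's membership column),
with ties broken toward the lower index. Both passes match literal
brute-force implementations exactly on 200-point clouds (asserted in the
suite and the acceptance script).

## Persistent cohomology

The Vietoris–Rips barcode of the landmark cloud is computed over Z_47
(47 is unlikely to divide any torsion subgroup; the suite spot-checks that
Z_2 gives the same barcode on the synthetic torus) with the cosine metric.
The engine is an in-package implementation of the standard persistent
cohomology algorithm: coboundary columns in reverse filtration order,
heap-based pivot extraction with modular arithmetic, the clearing
optimization, the emergent-pair shortcut, and a default filtration cutoff
at the enclosing radius (beyond it the complex is a cone, so nothing above
dimension 0 survives; this also prunes the dominant dimension-2 cost).
Simplices are encoded in the combinatorial number system; inner loops are
numba-compiled. Dimension-1 reduction stores the reduction-matrix columns,
whose entries are the representative cocycles. Correctness is established
against a naive textbook boundary-matrix reduction on random clouds (with
and without a cutoff) and against spaces with known homology.

Significance: each neuron's rate row is circularly rolled by an independent
uniform offset over the full recording, the whiten/downsample/persistence
path is rerun (clustering is not refit; the ensemble is held fixed, a
documented switch), and the per-dimension threshold is the 99th percentile
of maximal finite lifetimes over shuffles. Lifetimes are death - birth;
the infinite H0 bar is excluded. By construction at most ~1% of the null's
own draws exceed the threshold, which is the calibration property the
suite asserts; out-of-sample rolled surrogates exceed it at the expected
~1-2% per dimension.

## Circular coordinatization and decoding

For each chosen H1 bar the Z_47 representative cocycle is lifted to
integers in (-23, 23], restricted to the Rips 1-skeleton at
`tau = birth + 0.99 (death - birth)`, and smoothed by unweighted least
squares `min_f ||delta0 f - eta||` (sparse LSQR); vertex angles are
`2 pi (f mod 1)`. Edge-weighted smoothing is a possible refinement not
used here. On an evenly sampled noiseless circle the recovered map matches
the true angle to circular correlation > 0.99; on nonuniformly sampled
circles the harmonic map is a smooth reparameterization (correlation
~0.95-0.97), which is immaterial downstream because all comparisons are
gauge-aligned.

Extrapolation: for each circular dimension, every neuron's activity across
landmarks is binned over the landmark angles (16 bins, circular Gaussian
smoothing of 1 bin — the binning is not dictated by the source method; 16
matches the toroidal-phase binning) and normalized to a unit-mass circular
distribution. At each target time the distributions are summed weighted by
instantaneous activity and the angle is the circular mass center; zero
activity masks the sample. The per-neuron (rather than per-landmark)
reading is used because it alone supports decoding held-out sessions with
the same cells. Weights are the *raw* rates (the square of the
sqrt-transformed rates used for the metric): with sqrt weights the
landmark self-decode error is 6-8 degrees and truth correlation ~0.75,
with raw weights 3-4.5 degrees and ~0.97.

## Rate maps and toroidal phases

Spatial maps: 30x30 bins, occupancy-weighted means, unvisited bins filled
with the visited mean before a 2-bin Gaussian smooth. 1-D autocorrelograms
dot the binned tuning with zero-padded shifted copies (up to 300 bins).
Toroidal maps use 12-degree bins; the hexagonal 60-degree axis relation is
handled by shearing the first angle (`u = theta1 - theta2/2`) before
binning, tiling 3x3 copies for periodic smoothing, extracting the middle
tile and un-shearing row by row (fractional rolls, linear interpolation).
The 15-degree visualization shear of figure-style plots is deliberately
excluded from all numerical maps. Toroidal peak phases are per-axis
circular mass centers of the (default unsmoothed 16x16) binned activity;
antipodally balanced activity is flagged degenerate. With one sample per
bin the mass center reduces to the ordinary circular mean (asserted).

## Hexagonal torus classification

Heat kernels with a point source use the truncated lattice sum over
k, l in {-1, 0, 1} with diffusion time t = 0.1 and a 1/t prefactor; the
hexagonal quadratic form is `(2/sqrt(3))(x^2 + xy + y^2)` (the squared
norm of `x a1 + y a2` for unit lattice vectors 60 degrees apart), the
square form `x^2 + y^2`. The torus is parameterized on [0, 1)^2
internally; angles are divided by 2 pi at the module boundary.

Observed maps are unsmoothed 10x10 bin means of each unit's activity over
the *landmark* coordinates (pre-extrapolation). Model maps are bin means
of the kernel on an evenly sampled grid with the origin at the unit's peak
phase. Crucially, the decoded axes are only defined up to the unimodular
gauge group (orientation flips and lattice basis substitutions, rows from
{±(1,0), ±(0,1), ±(1,1), ±(1,-1)} with |det| = 1 — the same group that
cross-session alignment enumerates). Testing only the two axis
orientations misclassifies a hexagonal module whenever the decoder picked
a basis like (u, u+v): the correlation is therefore maximized over the
full gauge group, symmetrically for the hexagonal and square models. An
ensemble is hexagonal iff its median hex correlation exceeds 0.6 and the
square median. Pearson correlations are computed over all 100 bins without
occupancy weighting (the maps are already occupancy-averaged).

## Alignment, phase conservation, path length

Alignment candidates are the gauge matrices above; both coordinate series
are smoothed with a 200 ms circular Gaussian, per-axis offsets are
circular means of the residual, and the mean circular difference
(1 - cos) selects the transform. Planted transforms are recovered exactly
on noiseless data (the enumeration is exhaustive over the group).

Phase conservation: the mean flat-metric toroidal distance between matched
neurons' peak phases across sessions, against a null that permutes neuron
identities in one session (a uniform-rotation null is a documented
alternative; which the source analyses used is not stated);
`P = (1 + #{null <= observed}) / (n_shuffles + 1)`.

Unwrapping smooths the angles (0.2 s), then picks per step the
continuation minimizing the Euclidean jump among the four origin-crossing
combinations — equivalently the minimal wrapped representative per axis;
masked samples split the path into segments. Trial path length regresses
each axis on time, includes trials with |r| > 0.5 on both axes, and takes
the Euclidean distance between fitted endpoints, normalized by the mean
baseline length.

## Attractor simulators

All three models are noiseless and deterministic given a seed, and their
recurrent input is evaluated by FFT circular correlation over the sheet
(connectivity depends only on the difference of sheet coordinates), which
is exact — the suite verifies one FFT application equals the dense
weight-matrix product.

**Twisted/square torus.** Units sit on a regular grid in lattice-basis
(q) coordinates of R^2 / (Z a1 + Z a2) with a2 = (1/2, sqrt(3)/2)
(twisted) or (0, 1) (square); physical positions are the sheared image,
which is what makes the connectivity stationary on the rectangular
q-torus. The kernel is a Gaussian of the minimal flat-torus distance
(intensity 0.3, width 0.24) minus a constant inhibitory tail (0.05),
shifted by the velocity times `grid_gain` (default 0.06 per cm, i.e. a
~17 cm grid spacing). The update is `B = [A * K_v]_+` then
`A = B^q / mean(B^q)` with sharpening exponent q = 2 (pure divisive
normalization). The exponent is the package's choice where the source
model family's exact constants are not published: with a linear
normalization branch the 20x20 network either diverges (branch gain > 1)
or stabilizes stripes/multi-bump states instead of one bump. The state is
seeded with a single bump at a random center because the deterministic
dynamics conserve bump number — a symmetric two-bump state would never
resolve without noise. Verified properties: a single compact bump; exact
path integration (bump displacement equals the lattice-basis image of the
trajectory displacement times gain, with a constant ~0.5% discretization
slip, speed-independent); hexagonal spatial firing (rotational grid score
~ +1.05) for the twisted model and square firing (~ -1.05) for the square
model. `unit_phase_grid` returns each unit's q coordinates — genuine
circle coordinates of the sheet — and `bump_phase` reads the population
vector per axis, providing the decoding ground truth.

**Inhibitory sheet.** 56x44 units (default), purely inhibitory
connectivity: each cell inhibits with weight W0 = -0.01 an R = 20 disc
centered l = 2 sheet units along its *own* preferred direction (preferred
directions tile in 2x2 E/N/W/S blocks; the presynaptic offset convention
is essential — with the receiver-side convention the pattern does not
translate as a consistent linear function of velocity). Dynamics
`f <- f + (1/rho)(-f + [J + f.W + gamma s cos(phi - phi_pref)]_+)` with
J = 1, gamma = 0.15 per m/s (trajectory speeds in cm/s are converted via
`speed_scale` = 0.01; with raw cm/s the network is overdriven), rho = 10,
2 ms integration, rates below 1e-4 zeroed, output resampled at 10 ms,
random init plus 2000 zero-movement stabilization steps. The bracket is
rectification. Verified: fixed-point stability at zero velocity (< 1e-6
per-step change after extended stabilization), gamma = 0 equals the
zero-speed run, and pattern translation proportional to speed on straight
runs. *Known limitation:* on the default periodic sheet no equal-magnitude
hexagonal wavevector triad is commensurate, the stabilized state is a
two-mode pattern whose stripe systems slide non-rigidly, and the pattern
phase drifts relative to position over turning walks — so this model is
exercised for its dynamical properties while the torus models carry the
spatial-tuning and end-to-end claims.

**Trajectories.** The foraging generator uses heading diffusion
(0.6 rad/sqrt(s)) and an AR(1) speed around 15 cm/s (sd 5) at 10 ms steps
in a 150 cm box — typical rodent foraging statistics — with reflecting
walls (heading mirrored so the speed distribution is untouched). Speed and
heading are recomputed from positions, so the kinematic fields are
self-consistent by construction.

## Problem sizes and runtime

Default study sizes are chosen for a single CPU: the end-to-end runs use a
5000-frame (50 s) walk, 20x20 twisted / 10x10 square modules, and fuzzy
downsampling to 180 landmarks in the suite and 256 in the acceptance
script, with 5-20 shuffles for thresholds (100 for the acceptance null
calibration, the standard count for a 99th-percentile threshold). The
(1, 2, 1) signature, classification margins and 0.95+ decode correlations
are robust across seeds at these sizes. Persistence at 256 landmarks and
maxdim 2 takes ~15 s; dimension-2 reduction dominates.

## What the synthetic data does not emulate

The simulators are noiseless: no spiking variability, no out-of-module
contamination, no drift, no conjunctive tuning, and rates rather than
spike times feed the pipeline for the torus models. Passing tests
demonstrate the pipeline's correctness and calibration on clean toroidal
(and planted non-toroidal) structure; they do not establish robustness to
the noise level, cell-classification errors or nonstationarity of real
recordings, where the per-dataset parameter profiles (kernel widths,
epsilon/kappa/m, rho, speed threshold) matter.
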