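# Methods

## The method

`pathmetad` implements multiple-walker multiple-path metadynamics: several
cyclic adaptive paths are evolved in parallel in a collective-variable (CV)
space, each carrying its own group of walkers and its own shared
metadynamics bias on the normalized path progress `s`, with attractor
walkers holding each path in a chosen mechanism. The free-energy profile
along each path is the negative of the accumulated Gaussian bias, averaged
over late-time snapshots.

For the WCF-to-HG base-pair problem the CV space is
`[cos(chi'), sin(chi'), theta]`: the base-rolling angle chi' is embedded on
the unit circle so its 2-pi periodicity never enters a distance
computation, and the base-opening angle theta is linear. Sampled
configurations therefore live on the unit cylinder of that embedding. A
cyclic path starts and ends at the WCF anchor and describes a full
revolution of the rolling base; `s` grows from -1 to +1 and is periodic, so
WCF sits at `s = +/-1`, HG near `s ~ 0`, the 5' rotation at `s < 0` and the
3' rotation at `s > 0`.

## Path coordinates: two definitions, two jobs

The package deliberately carries two path-coordinate definitions.

*Piecewise-linear projection* (`project_point`, `projection_gradients`):
`s` is the arc-length progress of the nearest point on the polyline, `z`
the Euclidean distance to it. It is geometrically exact and testable
against a brute-force dense-resampling oracle, and it is what the analysis
and the projection tests use. It is, however, unusable as a *biasing*
coordinate: at every convex path corner there is a wedge of configurations
whose projection clips to the corner node, where `grad s = 0` exactly — a
bias force cannot be transmitted around corners, and finite differences
across the projection's medial-axis discontinuities produce unbounded force
spikes. Both failure modes were observed directly (walkers ejected from the
CV space; stationary densities off by ~1 kT around path corners).

*Smooth path CV* (`smooth_path_cv`): the field-standard soft-min
construction. Node `i` at arc fraction `a_i` carries the phase
`phi_i = pi + 2 pi a_i` and the weight `w_i = exp(-lambda d_i^2)`;

    s   = atan2(sum w sin phi, sum w cos phi) / pi,
    z^2 = softmin_i d_i^2 = -ln(sum w) / lambda,

both C1 with closed-form gradients (`grad z^2 = 2 (x - nbar)` with `nbar`
the weighted node mean). The engine biases this coordinate; the quadrature
reference bins by it (option `cv="smooth"`, the default), so estimate and
reference always refer to the same coordinate. The sharpness is
`lambda = 1 / (mean node spacing)^2`: sharper choices re-create corner
plateaus dynamically (the corner-apex `s` bins starve); much softer choices
blur genuine barrier structure.

## Bias, tube and restraints

Plain (non-tempered) metadynamics: hills of width 0.1 path units and height
0.05 kcal/mol are deposited every 1 ps by every standard walker, in walker
index order, into one shared list per path; evaluation uses the period-2
minimum image. The engine caches the bias on an 800-bin grid (exact
incremental hill addition, linear interpolation at evaluation); the exact
sum `bias_energy_force` is the reference implementation and the analysis
path. The tube potential is an upper harmonic wall at `z = 0` with
`k = 50` kcal/mol per squared path unit, applied through
`E = 1/2 k max(z^2, 0)` on the soft-min `z^2`.

Attractors: one walker restrained at the HG point (`k = 50`), two steered
to `s = +/-0.5` by a moving harmonic center over the first 20 ps
(`k = 5000`) and held at `theta = 0` (inside) or `theta = -pi/2` (outside)
with `k = 5000`. Attractors never deposit hills but their samples do drive
path updates — that is how they hold a path in its mechanism. The stiff
restraint forces are applied with the implicit-Euler factor
`1/(1 + k |grad q|^2 dt/gamma)` (the exact implicit solution for a linear
restraint), which keeps the overdamped integrator stable at any force
constant.

Hill deposition starts at t = 40 ps, twice the steering window: the
attractors must establish the two separated paths before the bias starts
pushing walkers over barriers. In the reference all-atom protocol this
ordering comes for free (diffusion onset lies two orders of magnitude
beyond the steering window); at desk scale it must be enforced.

## Path updates

Samples (all walkers, every step) are assigned to their nearest node (ties
to the lower index). Each node accumulates fading-memory sums of sample
positions and weights; a sample's weight halves every half-life (infinite
for inside paths — the path stiffens as statistics accumulate — and 20 ps
for outside paths). At each update (every 1 ps) an interior node moves
toward the perpendicular component of (weighted mean sample position -
node), capped at half the node spacing, followed by a neighbor-averaging
smoothing pass (fraction 0.2, a string-method stabilization against
node-scale kinks of the flexible path) and arc-length reparameterization.
Endpoints never move. For the rolling space, nodes are renormalized onto
the unit cylinder after each update, since that is the manifold the samples
live on. Reparameterization places nodes on the *original* polyline and
iterates their arc positions until consecutive chord lengths agree to 1e-6
relative, so repeated application cannot erode the geometry; a path with
all nodes coincident raises a state error.

The position-mean form of the update (rather than accumulating
displacement increments) matters: an increment formulation integrates
without bound under an infinite half-life, which lets a nominally rigid
path creep into a neighboring channel.

## The rotor-flip landscape

    V(chi', theta) = B(chi', theta) r(chi') + k_open theta^2 + tilt(chi')

with `r = [(1 - cos(chi' - chi_WCF))(1 - cos(chi' - chi_HG))]^1.5`,
normalized to 1 at the 3' mid-rotation. `B` interpolates between the inside
barrier scale (direction-dependent: `b_in_3p = 8.5`, `b_in_5p = 7.6`
kcal/mol, the 5' channel being further amplified by the rotor factor) and
the outside scale (`b_out = 4.6`, with a 0.15 extra 5' anisotropy) through
a Gaussian gate of width 0.45 rad centered at `theta = -pi/2`;
`k_open = 1.2` kcal/(mol rad^2); the tilt is a smoothstep raising the HG
basin by `delta_f_hg = 1.0` kcal/mol with vanishing curvature at the WCF
minimum, so the basin free-energy offset equals the parameter to ~0.01
kcal/mol. The defaults give exactly two minima at `(+/-1.5, 0)` and channel
barriers 7.7 (outside-3'), 8.9 (inside-3'), 11.2 (outside-5'), 12.2
(inside-5') kcal/mol — the ordering and magnitude range of the reference
system.

Three shape choices are load-bearing. The exponent 1.5 widens the stable
basins (thermal width ~0.4 rad) so the 0.1-wide hills can resolve them on
the long outside path, while keeping the barrier shoulders gentle enough
that `F(s)` contains no structure sharper than the hill width (with
quadratic-basin variants the profile develops sub-hill-width features that
a band-limited bias can never match). The gate width 0.45 rad keeps a
genuine inside channel floor near `theta = 0` at every rolling angle
(narrower gates destabilize it; wider ones merge the channels) and keeps
the path's flip corners round enough for the smooth CV. The barrier
magnitudes put the fill stage (~100 ps) well after attractor establishment.

## Dynamics and time bookkeeping

Overdamped Euler-Maruyama in `(chi', theta)`: `x <- x - grad U dt/gamma +
sqrt(2 kT dt/gamma) eta`, with `kT = 0.596` kcal/mol (300 K),
`gamma = 1`, `dt = 0.01`; chi' wraps to `[-pi, pi)`. One engine "ps" is 100
steps, so the reference schedule (1 ps hill/update pace, 20 ps steering)
carries over numerically. Walkers leaving the declared CV bounds (the
stable-state range plus pi plus a 3-rad margin on non-periodic axes) raise
a diagnostic error naming the walker. Every run artifact is a pure function
of (config, seed): each path consumes an independent stream spawned from
the root seed.

The default protocol runs 1400 ps per path pair with profile snapshots
every T/70 from 2T/7 to T (51 snapshots, the reference analysis ratios).
This length is the package's desk-scale choice: it keeps the whole two-path
study at a few minutes on one CPU while the bias-fluctuation error of the
averaged profiles stays at the ~0.2 kT level. The free-diffusion diagnostic
uses windows of one tenth of the analysis span and requires at least one
full WCF-HG-WCF traversal of the ensemble in every subsequent window.

## Free-energy analysis conventions

Each snapshot `F_t(s) = -sum of hills up to t` is min-shifted before
averaging (metadynamics fixes `F` only up to a growing constant; shifting
makes the per-bin standard deviation reflect shape, not fill level), and
the averaged profile is anchored to zero at the mean of the two edge (WCF)
bins. Barriers are the maxima of the anchored profile on `s < 0` (5') and
`s > 0` (3'); the HG minimum is located as the lowest interior point in
`|s| < 0.5` (its exact progress value cannot be assumed); a profile without
a genuine interior minimum yields a topology warning and an undefined
free-energy difference. The quadrature reference integrates
`exp(-[V + 1/2 k z^2]/kT)` on a dense `(chi', theta)` grid (480^2 default),
bins by the same smooth `s`, and its self-consistency check demands the
extracted barriers be stable to 0.05 kT under 2x grid refinement
(individual nearly-empty bins high on the barrier walls are not required to
converge bin-by-bin).

Run-to-run variability: the inside-path profile reproduces the quadrature
reference to ~0.15-0.3 kT RMS across seeds; the flexible outside path is
more variable (~0.2-0.4 kT typically, with occasional seeds reaching
~1-1.6 kT when the adaptation history leaves a stronger imprint in the
accumulated bias). The inside/outside consistency of the WCF-to-HG free-energy
difference is typically within 0.3 kT. A related intrinsic limit shows up
on a flat landscape, where the non-tempered shared bias keeps a slowly
wandering shape noise of ~1 kcal/mol amplitude at the reference deposition
rate; the package's time-averaged estimator halves it, and exact flatness
appears only in the slow-deposition limit.

## Double-channel benchmark

The generic landscape `V = a (x^2-1)^2 + c (y^2 - (1-x^2))^2` has two
minima at `(+/-1, 0)` joined by two symmetric channels hugging the unit
circle, with saddles of height `a = 1` and an inter-channel ridge
`a + c = 3`. A single 33-node cyclic path anchored at `(-1, 0)` is adapted
by the engine at `kT = 0.25` (a quarter of the saddle height — cold enough
that the sampled density ridge coincides with the minimum-energy path) and
compared against the zero-temperature string method (steepest descent with
reparameterization) started from the same initial circle.

## Structural CVs and fixtures

chi is the standard O4'-C1'-N9-C4 torsion (IUPAC sign convention, verified
against independent implementations). chi' is a pseudo-dihedral over four
mass-weighted centers; the shipped default — sugar COM (O4', C4') / C1' /
glycosidic-end base COM (N9, C4, C8) / six-ring COM — is a documented
convention, chosen for long torsion arms (a 0.2 A RMS coordinate noise
propagates to ~0.12 rad in chi') and because its third point lies on the
glycosidic axis, so a rotation of the base about that axis shifts chi' by
almost exactly the rotation angle. theta is a pseudo-dihedral over the 5'
flanking-pair bases, the 3' flanking-pair bases, the sugar and the six-ring
of the flipping purine; negative values open toward the major groove. Both
group sets are configurable (`AtomGroupSpec`); element masses are inferred
from the leading letter of the PDB atom name with an override table.

The fixture generator builds a synthetic idealized three-base-pair duplex
(C15-A16-A17 against G10-T9-T8, 3.4 A rise, 36 degree twist): bases use
standard planar reference-frame geometries; the pyrimidine partner is
placed by solving a rigid in-plane transform to exact pairing targets
(WCF: N1-N3 2.82 A, N6-O4 2.95 A, C1'-C1' 10.6 A; HG: N7-N3 2.9 A, N6-O4
3.0 A, C1'-C1' 9.1 A); the HG state is generated by rotating the adenine
base 180 degrees about the glycosidic axis; a planar furanose ring is
attached with its azimuth solved so chi' hits the state's characteristic
value; "flipped" swings the whole nucleotide about the helix axis through
its C1' toward the major groove. The `noise` parameter is the per-atom RMS
displacement in A (`sigma = noise/sqrt(3)` per coordinate), drawn from a
seeded generator. Classification (WCF if chi' within 0.6 rad of +1.5 and
d_WCF < 3.5 A; HG mirrored; else intermediate) round-trips the fixtures at
0.2 A noise.

What the fixtures do not emulate: sugar pucker, backbone phosphates,
sequence-dependent helix parameters, propeller/buckle, hydrogens and real
solvent structure. Passing fixture tests therefore validates the CV
*calculators* and the classification logic, not force-field geometries;
likewise the Langevin engine validates the sampling machinery, not DNA
energetics — the landscape is a constructed surrogate whose barrier
ordering and scale are inputs, not predictions.

## Known limitations

* The engine is 2D `(chi', theta)` with an analytic potential; no solvent,
  no atoms, no kinetics (overdamped dynamics has no physical time scale).
* Plain metadynamics only (no tempering); the profile estimator inherits
  its non-decaying bias fluctuations.
* One cyclic two-state path topology per path; no minor-groove channel, no
  multi-state paths.
* The outside path's flexibility (20 ps half-life) makes its converged
  geometry — and hence its profile — the least reproducible ingredient
  across seeds.
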