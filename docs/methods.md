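# Methods

## Scope and design

`elevatorfep` implements the complete enhanced-sampling free-energy stack
used to characterize the outward-facing ⇌ inward-facing (OF⇌IF) transition
of elevator transporters, at desk scale: the protein and its microsecond MD
are replaced by analytic landscapes and rigid-body bead systems propagated
with Brownian dynamics, chosen so that every estimator in the pipeline has
an exact or brute-force oracle. Passing tests therefore demonstrate the
*correctness of the estimators* under the statistical structure the real
analyses assume (metastable basins a few kcal/mol apart, harmonic biases,
two-state binding kinetics) — not the behavior of any real protein, force
field, or solvent model, which are entirely out of scope.

Units are fixed package-wide: Å, kcal/mol, ps, K, degrees. k_B = 1.987204
× 10⁻³ kcal/mol/K, so kT = 0.61603 kcal/mol at the 310 K used throughout.

## Synthetic systems

**1D double well.** U(x) = B_eff((x/a)² − 1)² + (α/2)(x/a + 1) with minima
at ±a = ±separation/2, barrier B above the left minimum, and asymmetry α
raising the right (IF-like) minimum. The "substrate" coupling δ enters as
B_eff = B − δ: the saddle drops by exactly δ while the minima stay fixed.
An earlier construction using a narrow Gaussian dip at the barrier top was
rejected because the dip's shoulders become the new profile maximum, so the
*measured* barrier difference is no longer the planted δ.

**2D two-basin elevator landscape.** Coordinates are span-normalized,
u = z/z_span (z_span = 8 Å) and v = θ/θ_span (θ_span = 19°), matching the
package-wide convention that any metric operation in mixed-unit CV space
(string arc length, window spacing, restraint energies) uses span-normalized
coordinates. The OF basin sits at (u,v) = (0,1) and IF at (1,0). With path
coordinate s = (u + 1 − v)/2 and transverse offset w,

U = 16·B_eff·s²(1−s)² + (k_t/2)(w − w₀(s))² + α·s,

where w₀(s) = A·sin(πs) curves the valley (A = 0.12 by default, so the
minimum free-energy path is genuinely curved and string refinement is not
trivial), k_t = 150 kcal/mol per unit² gives a transverse channel width
(σ_w ≈ 0.06) comparable to the CV fluctuations of a transporter basin, and
α = 1 kcal/mol (pipeline default) puts the IF basin above OF, as observed.
B_eff = B + confinement − δ: the substrate coupling δ lowers and the
confinement term (the anionic-lipid analog, default 2 kcal/mol) raises the
saddle by exactly their amplitudes, leaving basins and the transverse
stiffness — hence the vibrational entropy entering the free-energy profile
— untouched, so planted barrier *differences* between conditions are exact.
The three standard conditions are: apo (δ=0, confinement 2), substrate
(δ=3, confinement 2), and lipid-removed (δ=3, confinement 0), reproducing
the 3 kcal/mol substrate and 2 kcal/mol lipid-removal barrier shifts.

**Propagator.** Overdamped (Brownian) dynamics,
x ← x + μFΔt + √(2μkTΔt)·ξ with mobility μ = 1/(γm). An underdamped
integrator was rejected deliberately: every estimator in scope consumes
configurational statistics only, and the overdamped chain samples the same
Boltzmann distribution with one fewer tunable. The time unit is set by μ;
basin relaxation times are ~5–10 fs-equivalents, so "nanoseconds" of the
emulated workflow map to picoseconds here. A domain guard (|x| ≤ 10×
basin separation) converts divergence into an immediate error naming Δt.

**Elevator bead model.** A ring-like scaffold plus an anisotropic TD bead
cloud whose first principal axis is aligned with the y axis by
construction; the IF reference is the OF TD rigidly translated 8 Å along z
and rotated 19° about x (the geometry of the transporter this emulates).
Because the principal axis is perpendicular to the rotation axis, the θ CV
recovers the construction angle exactly, and the CV invariants (z(OF)=0,
z(IF)=8, θ(IF)=0, θ(OF)=19, invariance under global rigid motions) hold to
numerical precision.

**Telegraph binding.** Exact exponential dwell times drawn per state
(means 1/k_off bound, 1/(k_on[C]) unbound), chain started from its
stationary distribution, then sampled on a Δt grid. Defaults for the Kd
studies: k_on[C] = 0.036/ns, k_off = 0.1/ns at [C] = 18 mM — the planted
K_d = k_off/k_on = 50 mM at the physiological bicarbonate concentration —
with 10 µs series, 20 replicas.

## Collective variables and restraints

Frames are superposed onto the reference by the Kabsch algorithm on the
scaffold selection only (Cα-equivalents), with the reflection branch
corrected to a proper rotation. z is a *signed* projection (needed as a
monotone drive coordinate); θ uses the hemisphere convention (eigenvector
sign chosen for non-negative dot with the IF axis, range [0°, 90°]) to
resolve the sign ambiguity of principal axes. Restraints are harmonic,
U = ½k(value − c(t))²; θ restraints are applied to the span-normalized
coordinate, so a nominal z-force constant k (kcal/mol/Å²) maps to
k·z_span² per normalized unit² — the 36 kcal/mol/Å² umbrella constant
becomes 2304 in normalized units.

Nonequilibrium work integrates ∂U/∂t over the center schedule with the
trapezoid rule in the deviation, W += k·mean[(c−x)_start,(c−x)_end]·Δc:
this is exact both for an instantaneous center jump at fixed x (½kΔc²) and
for perfect tracking (zero), where one-sided discretizations fail.

## Driven stage

Drive duration defaults to 500 basin relaxation times (estimated from the
numeric curvature at the OF minimum), release half the drive — mirroring
the 2:1 drive/release shape of the emulated protocol. Sequential protocols
split the drive 50/50 between the CVs. The drive spring (k = 500
normalized) is deliberately stiffer than the transverse channel so that a
sequential protocol must actually pay the wall-climbing excursion instead
of corner-cutting. Convergence is judged on the time-averaged CVs over the
final 5% of the drive (a single end frame fluctuates thermally) against a
tolerance of 5% of the OF→IF span.

For *protocol comparison* the shared duration defaults to 100 relaxation
times: in the near-quasi-static regime all protocols' mean work collapses
onto ΔF and the comparison measures nothing, whereas at 100 τ dissipation —
which scales with the dragged path length and therefore separates the
protocols — dominates, and 100 pulls give a ≳6σ separation of the
simultaneous protocol's mean work from the sequential ones.

## String method (SMwST)

Protocol shape follows the emulated workflow: 32 images, 24 swarm replicas
per image, 200 cycles of restrained anchoring (k = 1000, 20 steps) plus
free drift (10 steps at Δt = 2×10⁻⁴), smoothing weight 0.1 every cycle,
reparametrization to equal arc length, endpoints fixed at the basin minima
(strings for different conditions share endpoints, as in the emulated
study). The free-stage length is the key noise/speed compromise: per-cycle
image noise is √(2kT·t_free/M), which at t_free = 2×10⁻³ keeps the
converged RMS drift (~0.010 normalized units/cycle) below the 1%-of-path-
length convergence threshold while the transverse contraction per cycle
(~k_t·t_free ≈ 0.3) still converges the string in well under 50 cycles.
The converged path is reported as the cycle-average over the trailing 50
cycles, the standard way of suppressing finite-swarm jitter. Replicas that
leave the domain guard are dropped and counted; >50% dropped at any image
is an error.

The validation oracle computes the zero-temperature MFEP by an entirely
independent route: minimize |∇U|² (Nelder–Mead) from the construction's
saddle, take the unstable Hessian eigenvector, and integrate normalized
steepest descent to both basins with overshoot-halving termination. For
the curved-valley landscape the converged finite-temperature string agrees
with this oracle to ≲0.007 normalized units at every image (tolerance
0.02, one grid cell).

## BEUS

64 windows at equal arc length along the refined path, k = 2304 normalized
(36 kcal/mol/Å² through the 8 Å span), giving adjacent-window overlap
≈ 0.5. Even/odd alternating sweeps of *center* swaps (the emulated
protocol swaps restraining centers, not configurations) by the Metropolis
rule; the force constant travels with the center. Samples are tagged by
the center active when recorded. Each replica runs 1200 sweeps of 100
steps (Δt = 10⁻⁴, sample stride 5, ~4 samples per correlation time), which
holds the window-to-window random-walk error of the reconstructed profile
to ≲0.1 kcal/mol at the barrier top — sized so the planted 3 and 2 kcal/mol
condition differences are recovered within ±0.3 across seeds. Acceptance
below 1% (cumulative) triggers a warning naming spacing/k.

Samples are projected to the 1D path coordinate by nearest-point projection
onto the piecewise-linear path, with *extrapolation* past the terminal
segments: clamping beyond-end samples into the end bins inflates their
apparent density (equi-s sets fan out into half-disks beyond an endpoint)
and was measured to bias the basin minimum by ~0.4 kcal/mol; with
extrapolation, beyond-end samples fall outside the [0,1] binning and are
simply excluded. The transverse component of the window bias is not
representable in 1D WHAM; along a path that tracks the valley floor it
contributes a nearly constant offset that cancels in profiles and exactly
cancels in condition differences.

## WHAM and errors

Histogram WHAM on 100 bins over s ∈ [0,1] (or the CV itself in 1D), bias
energy evaluated at bin centers. The self-consistent equations are solved
by L-BFGS on the (convex) WHAM likelihood with analytic gradient, then
polished by direct iteration until max|Δf| < 10⁻⁶ kcal/mol (itself the
convergence report); classic direct iteration, whose residual decreases
monotonically, remains available and is cross-checked against a
brute-force likelihood grid search on small problems. Windows must form a
connected chain through shared occupied bins; gaps are an error naming the
disconnected windows. Bins with fewer than `min_count` samples are
reported as NaN gaps, never interpolated.

Uncertainties: bootstrap across windows (the unit used by the emulated
study's error bars), 40 resamples by default, warm-started from the point
solution; a block-bootstrap-within-window mode and an integrated-
autocorrelation-time utility are provided for decorrelation-sensitivity
checks. Sample decorrelation before histogramming is handled by the
sampling stride at collection time.

## Binding analytics

Contacts: ligand within 3.5 Å (configurable) of any protein heavy atom,
via a per-frame k-d tree with an optional orthorhombic minimum-image mode
for real trajectories (the toy mode is non-periodic). Event segmentation
takes maximal constant-state runs; gap merging is off by default (K_d, a
ratio of totals, is insensitive to it, but k_on/k_off are not — it is
exposed as an explicit sensitivity knob). K_d = (t_unbound/t_bound)·[C]
with k_off = 1/⟨bound dwell⟩ and k_on = 1/(⟨unbound dwell⟩·[C]) reported
alongside; zero bound time raises an error rather than returning infinity.
Residue ranking uses fraction-of-all-frames as the default denominator
(with a bound-only option). Density grids normalize to visit probability
per frame per ligand, so maps from runs of different lengths are
comparable; maps are written in OpenDX with full-precision (`repr`) data
values so write→read round-trips are bit-exact.

## Pipeline, seeds, provenance

The pipeline executes drive → string refinement → BEUS → WHAM per
condition and then compares barriers (interior maximum minus starting-
basin minimum; a profile whose global maximum sits in a basin region is
flagged as having no interior barrier). A single global seed fans out to
every stage and replica through `numpy.random.SeedSequence` spawning; the
run record (config snapshot, stage seeds, package version, timestamps,
output paths) replays a run bit-identically. Configuration files are
strictly validated — unknown keys are rejected, not ignored.

Real-structure mode (`read_structure_selection`) loads Cα selections from
PDB files with 1-based inclusive `chain:first-last` ranges and reports
missing residues explicitly; it feeds the same CV machinery used by the
synthetic systems.

## Problem sizes

Defaults used by the test suite and the acceptance script: 16 windows ×
80k steps for the 1D WHAM fidelity study; 3 conditions × (driven transition
+ 200 SMwST cycles × 32 images × 24 replicas + 64 windows × 120k steps)
for the condition comparison; 100 pulls per protocol; 20 × 10 µs telegraph
series for K_d. These sizes were chosen so each estimator's statistical
error is several times smaller than the effect it must resolve; the whole
acceptance run takes a few minutes on one CPU.

## Known limitations

* The workflow runs in CV space; there is no atomistic backmapping, no
  explicit solvent/membrane, and no force-field physics.
* 1D-BEUS + WHAM along a curved path inherits the usual projection
  approximations (transverse bias component, Jacobian of the arc-length
  parametrization); these are ≲0.05 kcal/mol here and cancel between
  conditions, but would grow for strongly curved or branching paths.
* The K_d estimator reproduces the *estimator* of the emulated analysis,
  including its finite-sampling bias at short durations (measured to decay
  monotonically with duration); it does not model diffusion-limited
  rebinding or multiple ligands competing for one site.
* String endpoints are fixed at the basin minima; free-endpoint variants
  (needed if the basins themselves shift between conditions) are not
  implemented.
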