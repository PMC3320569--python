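# Methods

`ionpmf` reconstructs ion-permeation free-energy landscapes from
umbrella-sampling data and extracts the quantities a channel-permeation
study reports: basin free-energy differences, barriers along the minimum
energy path, and block-analysis error bars.  Because no public trajectory
data accompany the protocol it implements, every stage is validated against
synthetic data with analytically known ground truth.  This note records the
models, conventions, defaults and their rationale, and what the synthetic
validation does and does not establish.

Units throughout: kcal/mol (energy), Å (length), ps (time), K (temperature);
kT = 0.0019872041 · T kcal/mol, ≈ 0.596 kcal/mol at 300 K.

## The umbrella-sampling model

A window is a harmonic restraint U(x) = ½·k·Σᵢ(xᵢ−cᵢ)² on one or two axial
reaction coordinates (the ion's z-distance from the Thr175 / Leu176
carbonyl-oxygen ring centres, `d1` and `d2`).  The standard protocol is
k = 10 kcal/mol/Å², centres stepped every 1.0 Å, 0.5 ns per window sampled
once per picosecond, the first 50 ps discarded as equilibration (450
retained samples); 20 windows for the single-ion coordinate, a 270-window
grid for the two-ion map.  The ½-factor in the harmonic convention is fixed
package-wide (sampler, WHAM, file formats) — any consistent pair of
conventions is self-correcting, but file exchange needs one.

The 1D window range default is [−5, +14] Å relative to the Thr175 ring
(cavity to extracellular solution, 20 windows); the 2D default is a full
27 × 10 rectangular grid with an optional mask predicate for
non-rectangular coverage.

## WHAM

The PMF is F(ξ) = −kT ln p(ξ) with p obtained from the standard
self-consistent equations over per-window free-energy constants fᵢ
(bias energies evaluated at bin centres — the midpoint approximation).
Convergence is max |Δfᵢ| < 1e-7 kcal/mol, capped at 100 000 iterations; the
default "auto" mode switches to minimizing the equivalent convex
log-likelihood (L-BFGS in the reduced variables gᵢ = fᵢ/kT) when plain
iteration is slow, then polishes with the self-consistent update.  Default
bin widths are 0.1 Å (1D) and 0.25 Å per axis (2D): at least ten bins per
1.0 Å window step, balancing resolution against per-bin counts.

Unsampled bins are masked, never extrapolated.  Coverage is checked for
connectivity before solving: occupied bins within two bins of each other
(or co-occupied by one window) are considered coupled, since window tails
link near-adjacent bins through the bias weights; genuinely disconnected
coverage is an error listing the components.  No autocorrelation correction
is applied inside WHAM — statistical uncertainty is handled entirely by the
block procedure.

## Minimum energy path

The 2D PMF is interpolated with an interpolating bicubic spline (C¹
gradients; bilinear available).  Masked-out bins are filled by
nearest-neighbour relaxation purely to keep the spline smooth near the mask
boundary; they remain invalid query points.  The path is a 200-node string:
endpoints are relaxed to the nearest basin minima (discrete grid descent,
then bounded continuous refinement) and clamped; each iteration moves
interior nodes along the full negative gradient with an adaptive step
(max node displacement 0.2 bin widths per iteration, step floor at
1 kcal/mol/Å gradient scale) and reparametrizes the polyline to equal arc
length; iteration stops when the RMS node displacement between successive
paths falls below 1e-3 Å.

Two design points discovered during development:

* the *full-gradient* simplified-string step is used rather than a
  tangent-projected step: on a discrete path the projected variant can
  sustain transverse zig-zag modes (the central-difference tangent
  mis-projects short-wavelength perturbations) and stalls above the RMS
  stopping threshold, while the full step converges in ~100–200 iterations
  with an identical saddle;
* ΔG between adjacent path minima is stored as (forward − backward) so the
  barrier identity holds to the last floating-point bit.

Minima along the profile are merged when the intervening excursion rises
less than 0.25 kcal/mol above the higher minimum — below the smallest
uncertainty such analyses typically report, so no genuine feature is merged
away.  Barriers between adjacent minima A→B are forward = max F between −
F(A) and backward = max F between − F(B).  Note the downhill barrier may be
smaller than |ΔG|; only the uphill one must carry it.

As an independent cross-check (used in tests and the acceptance script,
never as the implementation), `grid_minimax_value` performs an exhaustive
Dijkstra-style minimax path search on a 0.05 Å grid; for a smooth two-basin
landscape its value equals the saddle height.

## Block errors

Each window's retained samples are cut into 3 consecutive, non-overlapping
blocks (150 ps each under the standard protocol; a sub-block remainder is
dropped from the end).  The full reconstruction — WHAM, plus the path
machinery for barrier quantities — is repeated per block; the reported
uncertainty is the sample (n−1) standard deviation of the three block
values, and the headline value is the full-data estimate.  The n−1
convention is the conservative small-n choice; the population variant is a
one-line toggle (`BlockScheme.ddof`).  Basin features are matched between
the full-data surface and the noisier block surfaces by searching for the
nearest local minimum within 1.5 Å of the full-data position.

Limitation, measured on synthetic data: when a window straddles a deep
narrow well its biased dynamics becomes bistable, with hopping times
comparable to the block length; the 3-block standard deviation is then
heavy-tailed and can overestimate the scatter of the full-data estimate
several-fold.  This is a property of block analysis on metastable windows,
not of this implementation, and it affects any study using the same error
procedure.  The calibration test therefore uses a landscape (2.0 kcal/mol
barrier, 0.8 Å wells) on which window sampling is ergodic within a block,
i.e. where the estimator's own assumption holds; there the pooled block
standard deviation brackets the true repeat-to-repeat scatter within its
stated factor.

## Synthetic data generator

The generator stands in for the MD engine and emulates exactly what the
analysis consumes: per-window reaction-coordinate series, Boltzmann
distributed on (landscape + bias) at 300 K, autocorrelated on the
picosecond scale, at a fixed recording stride.

*Landscapes* are sums of inverted Gaussian wells on a weak confining
quadratic background (0.02 kcal/mol/Å² curvature), calibrated numerically so
the requested barrier and basin asymmetry hold exactly at the stationary
points; the global minimum is normalized to zero.  The 1D background has a
flat bottom between the well centres — a centred quadratic would add a
spurious shallow third minimum between narrow wells.  The default 1D well
width is 0.4 Å (Gaussian σ; FWHM ≈ 0.94 Å), the sub-Ångström scale of
binding-site minima in filter PMFs; it also gives the biased windows the
occupancy the protocol's bin statistics assume (peak bins ≈ 120 counts at
0.1 Å bins).  The 2D wells are anisotropic: longitudinal width set to a
quarter of the basin separation, transverse width `valley_width`
(default 1.5 Å).  The construction is mirror-symmetric about the
inter-minimum axis, so its stationary points are exactly on that line.

*Dynamics* is overdamped Langevin integrated by Euler–Maruyama:
dx = −(D/kT)∇(F+U)dt + √(2Ddt)·ξ, with D = 0.1 Å²/ps (the order of an
aqueous ion diffusion coefficient), dt = 0.01 ps, stride 1 ps.  These give
relaxation times of a few tenths of a picosecond inside wells, so
consecutive retained samples are weakly correlated, matching the sampling
character the analysis expects.  Discretization biases the stationary
variance by a factor 2/(2−a) with a = D·dt·k_eff/kT (+0.8–4% here), which
is well below the statistical errors at 450 samples.  Walls at the domain
bounds are reflecting; a step overshooting the domain by more than 1 Å
aborts with an "unstable time step" error.

*Initialization*: each window's first sample is drawn from its biased
Boltzmann density (inverse CDF on a fine grid), emulating the practice of
seeding windows from an equilibrated configuration.  Starting at the bias
centre instead (available as `init="center"`) was observed to trap windows
on one side of a nearby well for entire blocks and inflate block errors.

Every generator output is a pure function of (parameters, seed); the
default provenance seed is 2012.  Per-window streams are independent
generators, so a window sampled inside a batch is bit-identical to the same
window sampled alone with its derived seed.

What the synthetic data does *not* emulate: orthogonal slow degrees of
freedom (protein conformational drift), multi-ion exchange with bulk during
a window, force-field energetics, and any real NavAb value.  Passing
recovery tests therefore demonstrates the correctness of the estimators
under the protocol's statistical conditions — not the accuracy of any
particular published free-energy number, which would require the original
trajectories.

## Structural analyses

Snapshots carry explicit atom roles (water O, backbone-carbonyl O of a
named residue, sidechain O, ion) rather than a topology.  Coordination
shells count oxygens strictly closer than 2.8 Å (Na⁺) or 3.2 Å (K⁺),
partitioned into water / backbone / Glu177 sidechain / Ser178 sidechain
(other sidechain oxygens are kept in a separate bucket so the partition
identity total = Σ sources always holds).  Radial displacement from the
pore axis (default: the z line through the backbone-carbonyl-O centroid) is
labelled by four contiguous axial bands delimited by the Thr175/Leu176
carbonyl rings and offsets around the Glu177 sidechain oxygens.  The cavity
water count uses a half-open axial slab with a strict radial cutoff;
the conventional region is the 8 Å slab below the Thr175 ring with a 6 Å
radius, configurable because the geometric definition of "the cavity" is a
modelling choice.  Frame subsampling picks the nearest frame within half
the native stride at 20 ps intervals after equilibration.

PDB I/O goes through biotite with a documented residue/atom-name mapping
(coordinates at the format's 3-decimal precision); the XYZ variant keeps
roles and identifiers verbatim in the comment line and round-trips exactly.

## Problem sizes in the validation suite

The test suite and the acceptance script run the protocol at its stated
sizes — 20-window 1D and 270-window 2D experiments with 450 retained
samples per window — since the vectorized sampler makes these cheap (the
full 2D study is ~125 k samples, tens of seconds).  Calibration tests that
need repeated full analyses (10 independent repeats, 3 reference
realizations) use the 1D protocol.  Properties that need ≥10⁵ samples
(goodness-of-fit of the sampler's stationary law) run several seeds as a
batch.

## Known limitations

* WHAM assumes retained samples are effectively independent; strongly
  metastable windows violate this and show up as inflated, heavy-tailed
  block errors (see above), not as biased means.
* The string method finds the MEP within the basin of attraction of its
  initial segment; landscapes with competing channels need multiple seeds.
* The interpolated surface near mask boundaries depends mildly on the
  neighbour-relaxation fill; paths hugging the sampled region's edge should
  be treated with caution.
* Band assignment and reaction coordinates assume the pore axis is aligned
  with z, as the frames produced by the generator guarantee; a
  principal-axis fit is not applied automatically.
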