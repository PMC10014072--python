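# Methods

## The steady-state model

Asters assembled by crosslinking kinesin motors are treated as radially
symmetric outside a disordered core of radius ≈15 μm. Motors exist in two
states: bound, walking along microtubules toward the aster center at
speed v, and free, diffusing with coefficient D. Binding is first order
in the local microtubule concentration, kon·ρMT(r)·m_f, and unbinding is
koff·m_b. Microtubules themselves are assumed stationary at steady state
(the aster has stopped contracting radially), so they act as a fixed
template ρMT(r) measured from the microtubule fluorescence channel.

With reflecting boundaries the total radial flux vanishes at steady
state, −v·m_b − D·dm_f/dr = 0, and in the fast-binding (local
equilibrium) limit m_b/m_f = ρMT/Kd with Kd = koff/kon. Eliminating m_b
gives the total motor concentration

    m_tot(r) = C · (1 + ρMT(r)/Kd) · exp( (1/λ0) ∫_r^{r_ref} ρMT(r')/Kd dr' ),

with λ0 = D/v and C the free-motor concentration at the reference radius
r_ref. The zero-total-flux relation is first order, so the closed form is
independent of whether the geometry is a slab, a cylinder or a sphere —
a property the test suite exercises explicitly. When the motor does not
walk (v → 0, λ0 → ∞) the exponential factor is 1 and the equilibrium
binding isotherm C(1 + ρMT/Kd) is recovered.

Assumptions worth keeping in mind: a single central z-slice stands in for
the 3-D aster; microtubule turning and angular motion are ignored; motor
crowding, jamming and collective processivity are absorbed into the
*effective* (Kd, λ0) rather than modelled — which is precisely what makes
the fitted values interesting to compare with single-molecule
expectations.

## The relaxation oracle

`relax_two_species_pde` integrates the governing bound/free equations
directly and is the independent check on the closed form. The spatial
discretization is finite-volume on uniform cells (spherical shells by
default): upwind advection of the bound species with linear in-cell
reconstruction of the donor value, centered diffusion of the free
species, zero-flux boundaries, pointwise reaction terms. The discrete
fluxes telescope, so total motor mass is conserved to machine precision
by construction (the tests require < 1e-6 relative drift end to end).

Two details matter numerically. First, plain donor-cell upwinding
carries numerical diffusion ~v·Δr/2 in the bound species; at 400 cells
over an 85 μm domain that alone distorts the steady profile by several
percent, defeating the purpose of a percent-level oracle, hence the
second-order reconstruction. Second, the fast-binding regime
(kon·ρ, koff ≫ v/Δr, D/Δr²) makes the system stiff: an explicit stepper
obeying the reaction CFL would need millions of steps. Time integration
therefore uses scipy's implicit BDF in doubling time chunks, declaring
steady state when max|∂m/∂t| drops below 1e-8 of its initial value. An
explicit Euler stepper at 0.9× the full CFL limit is retained
(`method="explicit"`) and cross-checked against BDF on small grids.

The oracle comparison is run over three microtubule profile families
(exponential, logistic with an inflection point, shoulder-modulated
exponential) × three (Kd, λ0) pairs chosen so the center-to-edge motor
enrichment spans ≈4–250×, the range seen in measured asters. The
residual deviation (≲0.5% sup-norm at 400 cells) mixes discretization
error with the genuine finite-rate departure from local equilibrium; the
latter shrinks as 1/koff, and the acceptance threshold of 2% is met with
margin.

## Profile extraction

Pixel centers sit at integer coordinates; distances are converted to μm
via the pixel size (default 0.65 μm, a 10× widefield scale). Radial bins
are half-open [kΔr, (k+1)Δr); wedge w of n covers angles
[2πw/n, 2π(w+1)/n) counter-clockwise from +x, so the wedges partition
the disk exactly. The aster center is the intensity-weighted centroid of
pixels above the 99th percentile after Gaussian smoothing; background is
the median over a far annulus (outermost 10% of the image by default, or
activation radius + 50 μm when the activation geometry is known).

Two deliberate splits: the aster-size statistic uses the *median* radial
profile (robust, matches the twice-background definition of the outer
radius), while model fitting uses the *mean* profile (smoother). The
default radial bin width for fitting is half a pixel; at one-pixel bins
the curvature of the profile across a bin leaves ≈1% bias on λ0, half-
pixel sampling pushes discretization bias well below the statistical
errors.

The outer-radius statistic scans outward from the 15 μm core cutoff for
the first crossing of 2× background, interpolating linearly between
bins, and ignores the trailing rise of the profile toward the
unactivated background by only searching up to the profile's global
minimum beyond the core.

## Inference

Kd and λ0 are optimized in log space (positivity for free); C is
multiplicative, so its optimum is closed-form for any (Kd, λ0) and is
profiled out, leaving a 2-D optimization run from a 4×4 multi-start grid
(Kd over decades of the inner microtubule value, λ0 over 1–1000 μm).

The default objective is least squares on *log* concentrations. Motor
concentrations span more than an order of magnitude across the fit
domain; under the multiplicative noise that camera images actually carry,
log residuals are the maximum-likelihood choice and weigh the dim outer
aster on an equal footing with the bright inner region. With unweighted
linear residuals (`objective="linear"`, retained for sensitivity checks)
the inner few bins dominate and the (Kd, λ0) errors at 5% noise are
several times larger. Bins are never imputed: missing bins are dropped.

Identifiability has a known boundary: when λ0 exceeds the fit-domain
width several-fold, the exponential factor degenerates toward 1, only Kd
is constrained, and the fit is flagged `equilibrium_consistent`. The
recovery study documents this regime (λ0 errors grow while Kd stays
within ~15%).

C is defined at the fit domain's outer edge. Comparing amplitudes
between fits with different domains requires re-referencing
(`rereference_amplitude`), which moves C by the exponential factor
accumulated between the two reference radii.

Wedge validation holds the shared (Kd, λ0) fixed and refits only each
wedge's amplitude (closed form). The fitting-error metric is the mean
absolute residual divided by the concentration at the inner boundary of
the fit domain.

## Contraction analysis

A quasi-one-dimensional network connecting two asters contracts like a
series of identical units: speed grows linearly with distance |x| from
the network center (fit through the origin by symmetry), and the maximum
aster speed scales with initial separation L as s·L/2. Aster speeds are
taken from central differences of (optionally moving-average-smoothed)
positions with second-order one-sided differences at the ends — the
maximum sits at t = 0 and a first-order edge difference would bias fast
contractions low at 15 s sampling. Only the first ≈100 s are scanned:
at later times motor unbinding and crosslink turnover make the network
viscous and the initial-rate picture breaks down (viscoelastic
relaxation is out of scope). The max-speed-vs-L fit keeps a free
intercept by default (`through_origin` is exposed); the slope ratios the
analysis reports are insensitive to that choice.

Gliding-assay speed is the mean of per-track path speeds (total path
length / duration) over tracks faster than a stuck threshold
(0.02 μm/s default); surface-pinned microtubules otherwise bias the
mean low, which one test demonstrates directly.

## Microscopic side calculations

`effective_speed_finite_mt` quantifies how finite filament length
reduces the effective bound-state speed: a motor lands uniformly along a
filament, walks with exponential run length ℓ, and stalls at the end
while its memoryless detachment clock continues. Per length L,
v_eff/v = 1 − (ℓ/L)(1 − e^{−L/ℓ}); the module evaluates this averaged
over a length distribution and cross-checks with direct Monte-Carlo
simulation. For K401-like inputs (ℓ ≈ 1 μm, median L ≈ 1.6 μm) this
stall model gives a reduction factor ≈2.0–2.2 depending on the length
distribution — larger than the ≈1.5 sometimes quoted for this effect,
suggesting a milder end-dwell rule (e.g. immediate unbinding at the end)
in other treatments; the factor is computed, never assumed.

`expected_kd_ratio` derives koff from speed and processivity
(koff = v / (8 nm × steps)) and combines it with caller-supplied binding
rates. For non-processive motors (Ncd) koff cannot be derived this way;
their Kd is meaningful only as a fitted effective parameter, and the
function refuses rather than guesses.

## The synthetic-data generator

The generator emulates the structures the analysis will meet in real
data and nothing more:

- **Microtubule profiles**: constant core plateau (default 15 μm), then
  a decay family (exponential; logistic with exactly one inflection
  point; shoulder-modulated exponential), approaching a constant
  background. An optional depletion cutoff sends the microtubule signal
  to zero beyond a radius, emulating the depleted zone between an aster
  and the unactivated background — without it, slowly decaying tails
  leak into the background annulus and bias the background estimate.
  When a target outer radius is requested, the decay scale is solved so
  the 2×background crossing lands there exactly (closed form for the
  exponential family, bracketed root-find otherwise).
- **Aster images**: both channels rendered by sampling the radial curves
  at each pixel-center radius, the motor channel computed from the
  steady-state model and scaled per 16-wedge sector; multiplicative
  Gaussian noise (default 5%, a shot-noise-like proxy — the real noise
  model is unknown) applied last. Benchmark conditions: amplitude 2,
  background 0.1 (a.u.), crossing at 85 μm, depletion at 100 μm,
  Kd = 0.5 (inner occupancy 4), λ0 = 20 μm, C = 1, 384² px at
  0.65 μm/px.
- **Merger trajectories**: positions ±(L/2)e^{−st} with s = α·v. The
  default α = 0.04 /μm reproduces the measured slopes (0.0023 1/s for
  Ncd, 0.0014 1/s for Kif11) from the Table-1 gliding speeds.
- **Gliding tracks**: per-track speeds ~ Normal(v, sd), a fixed stuck
  fraction jittering in place, 1 s sampling.

All randomness flows through one seeded generator per call; same seed,
bit-identical output. What the generator does *not* emulate — uneven
illumination, photobleaching, z-projection artefacts, optical-flow
estimation, aster formation dynamics — bounds what passing tests prove:
they validate the analysis chain against its own stated data model, not
against every artefact of real microscopy.

## Problem sizes

The default verification runs use 400 PDE cells, 384² px images, 50
noisy-fit replicates and 1e5 Monte-Carlo samples; the full suite runs in
about a minute and `scripts/acceptance.py` in about the same.

## Known limitations

- λ0 is unidentifiable beyond a few fit-domain widths (flagged, not
  hidden).
- The closed form assumes fast binding; systems where binding rates are
  comparable to transport rates deviate by O(v/(koff·Δr_profile)) and
  only the PDE route applies.
- Profiles with interior empty bins cannot enter the fit (uniform-bin
  contract); in practice empty bins occur only at the innermost radii,
  inside the excluded core.
- The contraction model covers the initial elastic regime only.
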