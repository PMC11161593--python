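# Methods

## Model overview

The package simulates a MINFLUX excitation module built from a variable
phase plate: an electro-optical modulator (EOM) imposing a voltage-controlled
phase φ between the vertical and horizontal polarization components, a
binary SLM whose 'on'-pixels act as a half-wave retarder, and a polarizer.
After the polarizer, the pupil carries a binary phase pattern whose step
height is φ, so the intensity minimum of the focused pattern can be scanned
by the EOM voltage alone. Three layers sit on top of each other:

1. a Jones-calculus model of the polarization chain,
2. a vectorial diffraction model of the focused excitation PSFs,
3. an estimation-theory layer (Fisher information / Cramér-Rao bound) and a
   Monte-Carlo photon-probing simulator.

## Polarization chain

States are Jones vectors in the horizontal/vertical frame; retarders use
the standard waveplate matrix W(φ, α) (phase delay φ, axis angle α), the
EOM is W(φ, 0) and the polarizer the projector diag(1, 0). Global phases
are dropped throughout; only intensities are contractual. Angles are
radians internally and degrees at every user interface.

SLM imperfections are parameterized by (dφ, dα) relative to the ideal
(π, 45°). Compensation searches the HWP angle α and EOM offset φ that
minimize the summed on+off field intensity after the polarizer — a smooth,
doubly periodic two-parameter landscape. The search is a 1°-step grid scan
(so the ideal configuration α = 45°, φ = π lies exactly on the grid; the
ideal SLM makes the zero set a degenerate curve and the grid point nearest
the conventional solution is kept) followed by Nelder-Mead refinement.
Residuals reach ~1e-22 across the modeled validity range |dφ| ≤ 0.3 rad,
|dα| ≤ 20°, i.e. compensation is complete to numerical precision. A
residual above tolerance is reported, not raised, so callers can map
residual landscapes. Mirror-induced s/p phase shifts are equivalent to an
extra diagonal retarder in the chain and are absorbed by the EOM offset,
which is why they need no dedicated element.

Two closed-form identities describe the non-ideal SLM axis at angle α:
a π retarder reflects the polarization about its axis, so the largest
achievable rotation of a linear state is 2α (67° at α = 33.5°), and
splitting the shortfall from the required 90° between the x and y patterns
leaves a best-case deviation of (90° − 2α)/2 = 11.5° from the optimal
(boundary-parallel) polarization of each pattern.

## Vectorial PSF computation

The focal field follows the vectorial Debye integral for an aplanatic
objective. The pupil is sampled on a symmetric, cell-centered Cartesian
(kx, ky) grid (default 256 samples across the aperture); each sample
carries

* the beam amplitude (flat or Gaussian profile, clipped by the aperture;
  defaults: 7.0 mm beam over a 6.5 mm aperture, flat),
* the mask phase, with the EOM phase added on the mask's 'on'-region,
* the apodization and measure factor 1/√cosθ,
* the 3×3 high-NA polarization rotation applied to the uniform input
  Jones vector.

Field values at focal points are chirp-z transforms (CZT) of the pupil
samples, which evaluates the diffraction sum on arbitrarily fine windows
(sub-nanometer if needed) without padding a global FFT grid; a brute-force
DFT oracle validates the CZT in the tests. The axial propagator is
exp(−i kz z); this sign orients z so that increasing the EOM phase beyond π
moves the top-hat minimum toward +z. The bisected masks put the EOM phase
on the negative half-pupil so the lateral displacement slope is positive
along the probed axis.

Masks: `flat`, `bisected_x`/`bisected_y` (phase step across the y/x axis),
`tophat` (inner disc against outer annulus; default inner radius R/√2,
which splits a flat beam into equal-energy halves — the equal-energy
condition a deep axial null requires), `vortex` (continuous azimuthal ramp;
no on-region, so the EOM phase is a global phase there) and `two_beam`
(two offset Gaussian beams with a relative phase, the interferometric
pattern). Default polarizations: boundary-parallel linear for the bisected
masks (the configuration that preserves a true zero at high NA), circular
for top-hat and vortex.

Normalization: every stack is divided by its total power (Parseval over the
pupil, z-invariant) and scaled so the flat-phase Airy reference of the same
configuration has maximum 1. Intensities are therefore in units of the
Airy peak I_A(0), and the "contrast" of a pattern is simply its minimum
value in these units. The Airy peak at the focus is polarization-
independent, so one reference serves all masks.

Numerical choices:

* Sub-voxel minima: 3-point parabolic interpolation of the axis profile;
  the 2 nm default voxel cannot otherwise resolve ~1.4 nm/deg slopes.
  A minimum on the window edge raises an error rather than returning a
  clipped value.
* Phase-to-displacement slopes are fitted over φ = π ± {5°, 10°, 15°, 20°}
  (least-squares line through the sub-voxel minima; non-monotonic
  displacement raises). Computed slopes at the reference configuration:
  1.41 nm/deg lateral (bisected), 3.73 nm/deg axial (top-hat).
* The top-hat high-NA zero is physically imperfect (~9e-4 of the Airy peak
  with the default inner radius); the bisected and vortex zeros are exact
  to numerical precision for their default polarizations.
* `scan_quality_curves` reports, per displacement, the minimum over the
  EOM phase of the intensity at the displaced position — the
  pinhole-plus-phase-ramp reading of a bench measurement. Beyond ~800 nm
  axial displacement the spatial minimum washes out entirely (PSF
  asymmetry), so a spatial-minimum definition would be undefined exactly
  where the degradation matters.

## Fisher information and CRB

A localization probes the emitter with K patterned beams; with p_i =
I_i/Σ_j I_j the Fisher matrix is J = N Σ_i (1/p_i)(∇p_i)(∇p_i)ᵀ and the
CRB is J⁻¹. Probabilities are built from probe intensities that include a
constant background offset b·I_A(0) (default b = 0.5%), which models both
an imperfect zero and sample background and guarantees p_i > 0. Gradients
are one-voxel central differences on the emitter-position grid, matching
the stored stacks. Reported precision is the dimension-averaged σ√N.

Scan patterns default to 3 probe positions per axis at −L/2, 0, +L/2
(L = 50 nm lateral, L_z = 150 nm axial). Probes whose axis matches the
mask's EOM scan axis are displaced *physically* — the EOM phase is set from
the fitted slope, so the PSF deforms as in the instrument; probes along
other axes (e.g. lateral displacement of the top-hat in the donut-only
pattern) are displaced rigidly by re-evaluating the focal window at shifted
coordinates (exact, no interpolation). A rigid-shift mode for all probes
exists as a fast approximation; near the pattern center the two agree to a
few percent. The full 3×3 J is always assembled; cross terms vanish at the
center by symmetry (verified in tests, not assumed).

Computed center precisions for the reference system (NA 1.35, n 1.406,
635 nm, b = 0.5%): 22.6 nm·√N for the 2D bilobed x+y pattern and
49.4 nm·√N for 3D with the top-hat z probes; the probe-set evaluation uses
a 5-point (2 nm) grid per axis around the center, and the numbers are
stable at finer grids.

## Monte-Carlo probing

Counts are independent Poisson draws per probe with mean proportional to
brightness × dwell × (I_i(r_E) + b·I_A(0)); for position estimation this is
equivalent to the multinomial conditioning used by the Fisher matrix.
The ML estimator maximizes Σ n_i ln p_i by grid search over the probe-set
grid plus per-axis parabolic refinement; on a 0.5 nm grid its ensemble
standard deviation reaches the CRB within 1% at N = 10⁴ photons.
All randomness flows through one numpy Generator with an explicit seed;
identical inputs and seed reproduce outcomes bit for bit.

EOM phase drift: a static error δ shifts every probe minimum by the
displacement slope, so probing a centered emitter with the drifted pattern
and estimating with the nominal model yields a bias of slope × δ to first
order (computed, not assumed: the simulator builds both probe sets). At
the reference configuration 0.2° ↦ 0.28 nm and 1.1° ↦ 1.55 nm laterally.

Fluorophore flicker is a symmetric two-state telegraph process (rates are
user parameters; dark-state physics is not modeled beyond this). Within
each dwell the brightness is weighted by the simulated on-state occupancy.
With a single probing cycle, slow flicker (rate ~0.2/µs against 1 µs
dwells) biases an off-center emitter's estimate by several nm; spreading
the same photon budget over 60 fast cycles averages the occupancy per
probe and the bias collapses to the Monte-Carlo noise floor. The study is
property-based (bias non-increasing with cycles); no quantitative flicker
bias is claimed.

Bench-style intensity traces use the two-path interference law
I ∝ 1 + cos(φ(t) − ξ) with ξ mapped from emitter position through the
displacement slope; ramp, three-level and dual-color (per-color EOM
offsets) waveforms are provided. These traces mimic the pinhole/photodiode
experiment qualitatively; measured bench contrasts and hardware timing are
outside the computational model.

## Synthetic fixtures and what tests show

`phaseplate.io.generate_fixtures` writes reduced stacks (33³ voxels at
8 nm, 96 pupil samples) for the flat, bisected and top-hat masks plus an
analytic 1D three-parabola probe model with its exact Fisher information
(floor 0.05, curvature 1e-3 nm⁻²; parameters chosen so one-step central
differences agree with the exact derivatives to 0.1%). The toy model and
the symbolic (sympy) oracle validate the finite-difference Fisher path
independently of the PSF engine.

The simulations emulate an ideal instrument: uniform illumination of a
perfect aperture, no wavefront aberrations, no SLM curvature or balancing,
no detector effects, and background reduced to a constant offset. Passing
tests therefore demonstrate the correctness of the optical and statistical
model, not the performance of any physical instrument; measured contrasts
of real benches are typically better than the worst-case polarization
bound computed here and worse than the ideal zeros.

## Known limitations

* The top-hat inner radius and the exact probe layout behind the published
  precision figures are not uniquely specified; defaults (R/√2, three
  probes per axis) are documented above and exposed as parameters.
* EOM wavelength dispersion is not modeled; different colors are different
  chain configurations with their own static offsets.
* No iterative multi-round MINFLUX photon-budget optimization; only
  single-round CRBs and localizations.
* No aberration retrieval or adaptive-optics correction.
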