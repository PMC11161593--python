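# phaseplate

Simulator of MINFLUX excitation with a **variable phase plate** — the
combination of an electro-optical modulator (EOM), a binary spatial light
modulator (SLM) and a polarizer that turns a binary pupil phase pattern
into one whose phase step φ can be scanned on the MHz time scale.

It is written for microscope builders and analysts who want to understand,
before building hardware, how such an excitation module performs: what the
bisected, top-hat and vortex pupil patterns look like at the focus of a
high-NA objective, how far the intensity minimum moves per degree of EOM
phase, how optical imperfections (SLM axis/retardance errors, polarization
mismatch, EOM phase drift) degrade the minimum, and what localization
precision a MINFLUX scan pattern built from these beams can reach.

## What it computes

**Polarization chain (Jones calculus).** A 45°-polarized beam passes the
EOM (variable retarder, vertical axis), an optional compensation half-wave
plate, the SLM ('on'-pixels ≈ HWP at 45°) and a horizontal polarizer. The
'on'-pixel light then carries the EOM phase φ and interferes with the
'off'-pixel light near the focus as

    I = E₀² (1 + cos(φ − ξ)),

where ξ is the position-dependent focal phase. Imperfect SLMs (retardance
π + dφ, axis 45° + dα) are nulled numerically by choosing the HWP angle
and EOM offset that minimize the summed on+off intensity.

**Vectorial PSFs.** Focal fields follow the vectorial Debye diffraction
integral, evaluated by chirp-z transforms of a sampled pupil (aplanatic
√cosθ apodization, full high-NA polarization mixing). Intensities are
normalized so the flat-phase Airy reference of equal total power has
maximum I_A(0) = 1.

**Localization precision.** For K probe intensities I_i(r_E) the counts
are multinomial with p_i = I_i / Σ_j I_j, the Fisher information is

    J(r_E) = N Σ_i (1/p_i) (∇p_i)(∇p_i)ᵀ,

and the Cramér-Rao bound is Σ_CRB = J⁻¹, reported as the dimension-averaged
single-photon precision σ√N with σ = √((CRB_x + CRB_y)/2) in 2D (analogous
in 3D). Background and imperfect zeros enter as an offset b · I_A(0).

**Monte Carlo.** Poisson photon counts, maximum-likelihood position
estimates, EOM-drift bias, and a telegraph-flicker study showing how fast
probing cycles average dark-state bias away.

## Worked example

```python
import math
import phaseplate as pp

config = pp.OpticalConfig()          # NA 1.35, n 1.406, 635 nm, flat 7 mm beam

# How far does the bisected-pattern minimum move per degree of EOM phase?
slope = pp.phase_to_displacement(config, pp.PhaseMask.bisected("x"))
print(f"lateral: {slope:.2f} nm/deg")
# lateral: 1.41 nm/deg

# Localization precision of the standard 2D MINFLUX pattern
sigma = pp.center_sigma(config, pp.standard_pattern_2d(L=50.0), b=0.005)
print(f"2D center precision: {sigma:.1f} nm*sqrt(N)")
# 2D center precision: 22.6 nm*sqrt(N)

# Can a half-wave plate null an SLM whose axis sits at 33.5 deg?
res = pp.compensate_slm(pp.SLMImperfection(0.0, math.radians(33.5 - 45.0)))
print(f"residual: {res.residual_intensity:.1e}")
# residual: 3.3e-23
```

The first number says a 1° EOM phase error displaces the beam minimum by
~1.4 nm — the stability budget of the modulator. The second is the
theoretical single-photon localization precision at the center of a
bilobed x+y scan pattern of 50 nm diameter with a 0.5% background offset:
with N detected photons the precision is 22.6/√N nm. The third confirms
that the compensation plate can null the imperfect SLM exactly.

The same computations are available from the shell:

```sh
phaseplate compensate --slm-axis-deg 33.5
phaseplate psf --mask bisected_x --phase-deg 190 --out psf.ome.tiff
phaseplate crb --pattern 3d_bilobed_tophat --L 50 --Lz 150 --b 0.005
phaseplate reproduce slopes
```

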