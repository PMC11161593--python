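"""Fisher information and Cramér-Rao bounds for MINFLUX scan patterns.

A MINFLUX localization probes a fluorophore at position r_E with K patterned
beams I_i whose minima sit at distinct positions.  With N photons in total
the counts are multinomial with probabilities

    p_i(r_E) = I_i(r_E) / sum_j I_j(r_E),

and the Fisher information matrix is

    J(r_E) = N sum_i (1/p_i) (grad p_i)(grad p_i)^T.

The CRB covariance is J^{-1}; the reported precision is the dimension
average sigma = sqrt(mean of the diagonal CRB entries), normalized to a
single photon as sigma * sqrt(N).

Background and imperfect zeros are modeled by adding a constant offset
b * I_A(0) to every probe PSF, where I_A(0) is the maximum of the
flat-phase Airy reference at equal total power (the PSF normalization of
:mod:`phaseplate.psf`, in whose units I_A(0) = 1).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from . import psf as _psf
from .psf import (OpticalConfig, PhaseMask, Polarization, PSFStack,
                  build_pupil, compute_psf, default_polarization,
                  phase_to_displacement)

__all__ = [
    "Probe",
    "ScanPattern",
    "ProbeSet",
    "PrecisionResult",
    "standard_pattern_2d",
    "standard_pattern_3d",
    "donut_pattern_2d",
    "vortex_pattern_2d",
    "add_background",
    "probe_intensities",
    "compute_probe_set",
    "fisher_matrix",
    "crb_map",
    "center_sigma",
    "compare_patterns",
    "sigma_profile",
]


@dataclasses.dataclass(frozen=True)
class Probe:
    """One probing exposure: a mask whose minimum sits at `position_nm` on `axis`."""

    mask: PhaseMask
    axis: str                 # "x" | "y" | "z"
    position_nm: float
    polarization: Optional[Polarization] = None

    def offset_vector(self) -> np.ndarray:
        v = np.zeros(3)
        v["xyz".index(self.axis)] = self.position_nm
        return v


@dataclasses.dataclass(frozen=True)
class ScanPattern:
    probes: Tuple[Probe, ...]
    L: float = 50.0           # lateral pattern diameter (nm)
    L_z: float = 150.0        # axial pattern diameter (nm)
    dims: int = 2

    def __post_init__(self) -> None:
        if len(self.probes) < 2 * self.dims:
            raise ValueError("need at least 2 probes per estimated dimension")


def _axis_probes(mask: PhaseMask, axis: str, diameter: float,
                 n: int = 3, polarization=None) -> Tuple[Probe, ...]:
    positions = np.linspace(-diameter / 2.0, diameter / 2.0, n)
    return tuple(Probe(mask, axis, float(p), polarization) for p in positions)


def standard_pattern_2d(L: float = 50.0, n_per_axis: int = 3) -> ScanPattern:
    """Sequential bilobed x + bilobed y probing, minima at -L/2, 0, +L/2."""
    probes = (_axis_probes(PhaseMask.bisected("x"), "x", L, n_per_axis)
              + _axis_probes(PhaseMask.bisected("y"), "y", L, n_per_axis))
    return ScanPattern(probes, L=L, dims=2)


def standard_pattern_3d(L: float = 50.0, L_z: float = 150.0,
                        n_per_axis: int = 3) -> ScanPattern:
    """Bilobed x + bilobed y + top-hat z probing."""
    probes = (_axis_probes(PhaseMask.bisected("x"), "x", L, n_per_axis)
              + _axis_probes(PhaseMask.bisected("y"), "y", L, n_per_axis)
              + _axis_probes(PhaseMask.tophat(), "z", L_z, n_per_axis))
    return ScanPattern(probes, L=L, L_z=L_z, dims=3)


def donut_pattern_3d(L: float = 50.0, L_z: float = 150.0,
                     n_per_axis: int = 3) -> ScanPattern:
    """'3D donut' (top-hat) probing in all three directions.

    The top-hat minimum is scanned axially by the EOM phase but must be
    displaced rigidly (beam deflection) for the lateral probes.
    """
    th = PhaseMask.tophat()
    probes = (_axis_probes(th, "x", L, n_per_axis)
              + _axis_probes(th, "y", L, n_per_axis)
              + _axis_probes(th, "z", L_z, n_per_axis))
    return ScanPattern(probes, L=L, L_z=L_z, dims=3)


def donut_pattern_2d(L: float = 50.0, n_per_axis: int = 3) -> ScanPattern:
    th = PhaseMask.tophat()
    probes = (_axis_probes(th, "x", L, n_per_axis)
              + _axis_probes(th, "y", L, n_per_axis))
    return ScanPattern(probes, L=L, dims=2)


def vortex_pattern_2d(L: float = 50.0, n_per_axis: int = 3) -> ScanPattern:
    """Lateral donut (vortex) probing, rigidly displaced."""
    vx = PhaseMask.vortex()
    probes = (_axis_probes(vx, "x", L, n_per_axis)
              + _axis_probes(vx, "y", L, n_per_axis))
    return ScanPattern(probes, L=L, dims=2)


# ---------------------------------------------------------------------------
# probe intensities
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProbeSet:
    """Probe intensities I_i and probabilities p_i on an emitter-position grid.

    intensities has shape (K, nx, ny, nz) and already includes the
    background offset b (in I_A(0) units, where I_A(0) = 1).
    """

    intensities: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    b: float = 0.0
    pattern: Optional[ScanPattern] = None

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("background fraction b must be non-negative")
        if np.any(self.intensities < 0):
            raise ValueError("probe intensities must be non-negative")

    @property
    def probabilities(self) -> np.ndarray:
        total = self.intensities.sum(axis=0)
        return self.intensities / total

    @property
    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.x, self.y, self.z

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    def center_index(self) -> Tuple[int, ...]:
        return tuple(s // 2 for s in self.intensities.shape[1:])

    def at(self, position: Sequence[float]) -> np.ndarray:
        """Interpolated probe intensities at an emitter position (nm)."""
        pos = np.asarray(position, dtype=float)
        out = np.empty(self.n_probes)
        pts = [ax for ax in self.axes]
        for i in range(self.n_probes):
            interp = RegularGridInterpolator(
                pts, self.intensities[i], method="linear", bounds_error=True)
            out[i] = interp(pos)[0]
        return out


def add_background(stack: PSFStack, b: float) -> PSFStack:
    """Return a copy of `stack` with the offset b * I_A(0) added everywhere."""
    if b < 0:
        raise ValueError("background fraction b must be non-negative")
    meta = dict(stack.meta)
    meta["background_b"] = meta.get("background_b", 0.0) + b
    return PSFStack(stack.data + b, stack.x, stack.y, stack.z,
                    stack.voxel_size_nm, meta)


def probe_intensities(
    pattern: ScanPattern,
    psfs: Sequence[PSFStack],
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    b: float = 0.0,
) -> ProbeSet:
    """Probe set from precomputed PSF stacks via shifted interpolation.

    I_i(r_E) = I(r_E - r_i): each probe's stack (computed with its minimum at
    the origin) is evaluated at the shifted emitter positions by linear
    interpolation.  The stacks must cover the requested grid plus shifts.
    """
    if len(psfs) != len(pattern.probes):
        raise ValueError("one PSF stack per probe required")
    x, y, z = (np.atleast_1d(np.asarray(a, dtype=float)) for a in (x, y, z))
    K = len(pattern.probes)
    out = np.empty((K, len(x), len(y), len(z)))
    XX, YY, ZZ = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([XX, YY, ZZ], axis=-1)
    for i, (probe, stack) in enumerate(zip(pattern.probes, psfs)):
        interp = RegularGridInterpolator(
            (stack.x, stack.y, stack.z), stack.data,
            method="linear", bounds_error=True)
        try:
            out[i] = interp(pts - probe.offset_vector())
        except ValueError as err:
            raise ValueError(
                "evaluation grid extends beyond the PSF support for probe "
                f"{i} at {probe.position_nm} nm along {probe.axis}") from err
    return ProbeSet(out + b, x, y, z, b=b, pattern=pattern)


def compute_probe_set(
    config: OpticalConfig,
    pattern: ScanPattern,
    b: float = 0.005,
    x: Optional[np.ndarray] = None,
    y: Optional[np.ndarray] = None,
    z: Optional[np.ndarray] = None,
    mode: str = "eom",
) -> ProbeSet:
    """Compute probe intensities by direct PSF evaluation.

    mode "eom": probes whose axis matches the mask's EOM scan axis are
    displaced physically by setting the EOM phase from the fitted
    phase-to-displacement slope (the minimum moves, the PSF deforms
    faithfully); probes along other axes are displaced rigidly.  mode
    "shift" displaces every probe rigidly (fast approximation).  Rigid
    displacement is exact here: the focal window is re-evaluated at shifted
    coordinates rather than interpolated.
    """
    if mode not in ("eom", "shift"):
        raise ValueError("mode must be 'eom' or 'shift'")
    step = config.voxel_size_nm
    if x is None:
        x = np.arange(-2, 3) * step
    if y is None:
        y = np.arange(-2, 3) * step
    if z is None:
        z = np.arange(-2, 3) * step if pattern.dims == 3 else np.array([0.0])
    x, y, z = (np.atleast_1d(np.asarray(a, dtype=float)) for a in (x, y, z))

    K = len(pattern.probes)
    out = np.empty((K, len(x), len(y), len(z)))
    for i, probe in enumerate(pattern.probes):
        use_eom = mode == "eom" and probe.mask.scan_axis == probe.axis
        phase = math.pi
        axes = [x, y, z]
        if use_eom and probe.position_nm != 0.0:
            slope = phase_to_displacement(config, probe.mask, probe.axis)
            phase = math.pi + math.radians(probe.position_nm / slope)
        elif probe.position_nm != 0.0:
            # rigid displacement: evaluate the pi-phase PSF at r_E - r_i
            ia = "xyz".index(probe.axis)
            axes[ia] = axes[ia] - probe.position_nm
        pupil = build_pupil(config, probe.mask, probe.polarization, phase)
        fields = _psf.focus_field(pupil, *axes)
        intensity = np.sum(np.abs(fields) ** 2, axis=0)
        scale = (_psf._flat_total_power(config) / pupil.total_power
                 / _psf.airy_peak(config))
        out[i] = intensity * scale
    return ProbeSet(out + b, x, y, z, b=b, pattern=pattern)


# ---------------------------------------------------------------------------
# Fisher information and CRB
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PrecisionResult:
    """Fisher matrices, CRB covariance and sigma*sqrt(N) over the interior grid."""

    fisher: np.ndarray            # (nx', ny', nz', 3, 3); zero rows for flat axes
    x: np.ndarray                 # interior axes where gradients exist
    y: np.ndarray
    z: np.ndarray
    n_photons: float
    grad_axes: Tuple[int, ...]    # axes along which gradients were available
    crb_covariance: Optional[np.ndarray] = None
    sigma_single_photon: Optional[np.ndarray] = None
    dims: Optional[int] = None
    n_singular: int = 0

    def center_index(self) -> Tuple[int, ...]:
        return tuple(s // 2 for s in self.fisher.shape[:3])

    @property
    def center_sigma(self) -> float:
        if self.sigma_single_photon is None:
            raise ValueError("run crb_map first")
        return float(self.sigma_single_photon[self.center_index()])


def fisher_matrix(probe_set: ProbeSet, n_photons: float = 1.0) -> PrecisionResult:
    """Fisher information from central finite differences of p_i.

    The gradient step is one grid step per axis (the stored voxel size);
    axes with fewer than three points carry no gradient and contribute zero
    rows/columns.  Requires p_i > 0 on the interior, which a positive
    background offset guarantees.
    """
    p = probe_set.probabilities
    axes = probe_set.axes
    grad_axes = tuple(i for i, ax in enumerate(axes) if len(ax) >= 3)
    if not grad_axes:
        raise ValueError("no axis with >= 3 points to differentiate along")
    interior = tuple(
        slice(1, -1) if i in grad_axes else slice(None) for i in range(3)
    )
    p_in = p[(slice(None),) + interior]
    if np.any(p_in <= 0):
        raise ValueError(
            "p_i = 0 on the evaluation region; use a positive background "
            "offset b or shrink the region to the PSF interior")
    shape = p_in.shape[1:]
    grads = np.zeros((p.shape[0],) + shape + (3,))
    for ax in grad_axes:
        h = axes[ax][1] - axes[ax][0]
        lo = tuple(slice(0, -2) if i == ax else interior[i] for i in range(3))
        hi = tuple(slice(2, None) if i == ax else interior[i] for i in range(3))
        grads[..., ax] = (p[(slice(None),) + hi] - p[(slice(None),) + lo]) / (2 * h)
    J = n_photons * np.einsum("k...i,k...j->...ij", grads / p_in[..., None], grads)
    J = 0.5 * (J + np.swapaxes(J, -1, -2))  # enforce exact symmetry
    return PrecisionResult(
        fisher=J,
        x=axes[0][interior[0]], y=axes[1][interior[1]], z=axes[2][interior[2]],
        n_photons=n_photons, grad_axes=grad_axes,
    )


def crb_map(result: PrecisionResult, dims: int = 2) -> PrecisionResult:
    """Invert the Fisher matrices and fill in the sigma*sqrt(N) map.

    dims selects the estimated coordinates: 1 (x only), 2 (x, y) or 3.
    Singular matrices yield NaN entries; their count is reported in
    `n_singular`.  sigma is the dimension-averaged single-photon precision
    sqrt(mean(CRB diagonal)) * sqrt(N).
    """
    if dims not in (1, 2, 3):
        raise ValueError("dims must be 1, 2 or 3")
    sub = result.fisher[..., :dims, :dims]
    shape = sub.shape[:-2]
    cov = np.full_like(sub, np.nan)
    sigma = np.full(shape, np.nan)
    flat = sub.reshape(-1, dims, dims)
    cov_flat = cov.reshape(-1, dims, dims)
    sig_flat = sigma.reshape(-1)
    n_singular = 0
    for i, J in enumerate(flat):
        try:
            c = np.linalg.inv(J)
        except np.linalg.LinAlgError:
            n_singular += 1
            continue
        if not np.all(np.isfinite(c)) or np.any(np.diag(c) < 0):
            n_singular += 1
            continue
        cov_flat[i] = c
        sig_flat[i] = math.sqrt(np.trace(c) / dims)
    result.crb_covariance = cov
    # sigma computed at N photons; normalize to a single photon
    result.sigma_single_photon = sigma * math.sqrt(result.n_photons)
    result.dims = dims
    result.n_singular = n_singular
    return result


def center_sigma(
    config: OpticalConfig,
    pattern: ScanPattern,
    b: float = 0.005,
    mode: str = "eom",
) -> float:
    """Dimension-averaged sigma*sqrt(N) at the pattern center."""
    probe_set = compute_probe_set(config, pattern, b=b, mode=mode)
    res = crb_map(fisher_matrix(probe_set), dims=pattern.dims)
    return res.center_sigma


def sigma_profile(
    config: OpticalConfig,
    pattern: ScanPattern,
    offsets_nm: np.ndarray,
    axis: str = "x",
    b: float = 0.005,
    mode: str = "eom",
) -> pd.DataFrame:
    """sigma*sqrt(N) vs emitter distance from the pattern center along `axis`."""
    offsets_nm = np.asarray(offsets_nm, dtype=float)
    step = config.voxel_size_nm
    lo, hi = offsets_nm.min(), offsets_nm.max()
    ia = "xyz".index(axis)
    line = np.arange(lo - step, hi + step + step / 2, step)
    axes = [np.arange(-1, 2) * step] * 3
    if pattern.dims == 2:
        axes[2] = np.array([0.0])
    axes[ia] = line
    probe_set = compute_probe_set(config, pattern, b=b,
                                  x=axes[0], y=axes[1], z=axes[2], mode=mode)
    res = crb_map(fisher_matrix(probe_set), dims=pattern.dims)
    pts = (res.x, res.y, res.z)[ia]
    sig = res.sigma_single_photon
    idx = [s // 2 for s in sig.shape]
    prof = []
    for off in offsets_nm:
        j = int(np.argmin(np.abs(pts - off)))
        sel = list(idx)
        sel[ia] = j
        prof.append({"offset_nm": float(pts[j]),
                     "sigma_single_photon_nm": float(sig[tuple(sel)])})
    return pd.DataFrame(prof)


def compare_patterns(
    config: OpticalConfig,
    patterns: dict,
    b: float = 0.005,
    mode: str = "eom",
) -> pd.DataFrame:
    """Ranked table of center sigma*sqrt(N) for named scan patterns.

    All patterns are evaluated under the same background offset and PSF
    normalization, so the center precisions are directly comparable.
    """
    rows = []
    for name, pattern in patterns.items():
        rows.append({
            "pattern": name,
            "dims": pattern.dims,
            "L_nm": pattern.L,
            "L_z_nm": pattern.L_z,
            "b": b,
            "center_sigma_single_photon_nm": center_sigma(
                config, pattern, b=b, mode=mode),
        })
    df = pd.DataFrame(rows).sort_values(
        "center_sigma_single_photon_nm", ignore_index=True)
    return df
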