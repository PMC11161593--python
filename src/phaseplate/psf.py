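"""Vectorial excitation PSFs from pupil phase masks.

The focal field of a high-NA objective is computed from the vectorial Debye
diffraction integral.  The pupil is sampled on a Cartesian (kx, ky) grid
inside the aperture; each sample carries the beam amplitude, the mask phase
(plus the EOM phase on the 'on'-region), the aplanatic apodization and the
polarization rotation into the three Cartesian field components.  The field
at chosen focal-region points is then a chirp-z transform (CZT) of the pupil
samples, which evaluates the diffraction sum on an arbitrarily fine focal
window without zero-padding a full FFT grid.

Conventions
-----------
* Focal-space coordinates in nm, pupil-space in mm; angles in radians.
* Intensities are normalized so the flat-phase (Airy) reference PSF of the
  same optical configuration and equal total power has maximum 1, i.e.
  values are in units of the Airy peak I_A(0).
* The EOM phase is carried by the mask's 'on'-region.  The on-region is the
  kx < 0 (ky < 0) half pupil for the bisected x (y) masks and the inner disc
  for the top-hat mask; with the chosen axial phase sign this makes the
  minimum displacement per degree of EOM phase positive along the probed
  axis for all three masks.
"""

from __future__ import annotations

import dataclasses
import functools
import math
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import czt

__all__ = [
    "OpticalConfig",
    "PhaseMask",
    "Polarization",
    "PupilField",
    "PSFStack",
    "default_polarization",
    "build_pupil",
    "focus_field",
    "compute_psf",
    "airy_peak",
    "minimum_position",
    "phase_to_displacement",
    "contrast",
    "scan_quality_curves",
    "MinimumOnBoundaryError",
]

SQRT2 = math.sqrt(2.0)


class MinimumOnBoundaryError(ValueError):
    """The intensity minimum fell on the edge of the computed grid."""


# ---------------------------------------------------------------------------
# configuration and mask types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class OpticalConfig:
    """Physical parameters of the focusing system.

    Defaults describe the reference system: a 100x objective with NA 1.35,
    aperture diameter 6.5 mm, refractive index 1.406 of immersion and
    mounting media, wavelength 635 nm, 7.0 mm flat-profile beam, 2 nm voxels.
    """

    numerical_aperture: float = 1.35
    refractive_index: float = 1.406
    wavelength_nm: float = 635.0
    aperture_diameter_mm: float = 6.5
    beam_diameter_mm: float = 7.0
    beam_profile: str = "flat"          # "flat" | "gaussian"
    voxel_size_nm: float = 2.0
    grid_shape: Tuple[int, int, int] = (65, 65, 65)
    pupil_samples: int = 256

    def __post_init__(self) -> None:
        if self.numerical_aperture >= self.refractive_index:
            raise ValueError("numerical_aperture must be below refractive_index")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel_size_nm must be positive")
        if any(s % 2 == 0 or s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be odd in each axis")
        if self.beam_profile not in ("flat", "gaussian"):
            raise ValueError(f"unknown beam_profile {self.beam_profile!r}")
        if self.pupil_samples < 16:
            raise ValueError("pupil_samples too small")

    @property
    def k_medium(self) -> float:
        """Wavenumber in the immersion medium, rad/nm."""
        return 2 * math.pi * self.refractive_index / self.wavelength_nm

    @property
    def sin_theta_max(self) -> float:
        return self.numerical_aperture / self.refractive_index

    @property
    def k_max(self) -> float:
        """Transverse wavenumber at the aperture edge, rad/nm."""
        return self.k_medium * self.sin_theta_max


@dataclasses.dataclass(frozen=True)
class PhaseMask:
    """Pupil-plane phase pattern.

    kinds: flat, bisected_x, bisected_y, tophat, vortex, two_beam.
    The bisected masks split the aperture along a line through the center
    (boundary along y for bisected_x); tophat offsets an inner disc against
    the outer annulus; vortex imposes a continuous azimuthal phase ramp (no
    on-region, so the EOM phase is global there); two_beam is the
    interferometric pattern made of two offset Gaussian beams.
    """

    kind: str = "flat"
    tophat_radius_fraction: float = 1.0 / SQRT2  # equal-area inner disc
    two_beam_diameter_mm: float = 2.3
    two_beam_offset_mm: float = 2.3
    two_beam_relative_phase: float = math.pi

    KINDS = ("flat", "bisected_x", "bisected_y", "tophat", "vortex", "two_beam")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if not 0.0 < self.tophat_radius_fraction < 1.0:
            raise ValueError("tophat_radius_fraction must be in (0, 1)")

    # convenience constructors ------------------------------------------------
    @classmethod
    def flat(cls) -> "PhaseMask":
        return cls("flat")

    @classmethod
    def bisected(cls, axis: str) -> "PhaseMask":
        if axis not in ("x", "y"):
            raise ValueError("bisected axis must be 'x' or 'y'")
        return cls(f"bisected_{axis}")

    @classmethod
    def tophat(cls, radius_fraction: float = 1.0 / SQRT2) -> "PhaseMask":
        return cls("tophat", tophat_radius_fraction=radius_fraction)

    @classmethod
    def vortex(cls) -> "PhaseMask":
        return cls("vortex")

    @property
    def scan_axis(self) -> Optional[str]:
        """Axis along which the EOM phase displaces the minimum, if any."""
        return {"bisected_x": "x", "bisected_y": "y", "tophat": "z",
                "two_beam": "x"}.get(self.kind)


@dataclasses.dataclass(frozen=True)
class Polarization:
    """Uniform pupil polarization: linear at `angle` rad from x, or circular."""

    kind: str = "linear"  # "linear" | "circular"
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "circular"):
            raise ValueError(f"unknown polarization kind {self.kind!r}")

    def jones(self) -> Tuple[complex, complex]:
        if self.kind == "circular":
            return (1.0 / SQRT2, 1j / SQRT2)
        return (math.cos(self.angle), math.sin(self.angle))

    @classmethod
    def linear_deg(cls, angle_deg: float) -> "Polarization":
        return cls("linear", math.radians(angle_deg))

    @classmethod
    def circular(cls) -> "Polarization":
        return cls("circular")


def default_polarization(mask_kind: str) -> Polarization:
    """Circular for the 3D donut (top-hat) and vortex, linear otherwise.

    Bisected masks get the boundary-parallel linear polarization that
    preserves a true zero at high NA: along y for bisected_x (boundary is
    the y axis) and along x for bisected_y.
    """
    if mask_kind in ("tophat", "vortex"):
        return Polarization.circular()
    if mask_kind == "bisected_x":
        return Polarization("linear", math.pi / 2)
    return Polarization("linear", 0.0)


# ---------------------------------------------------------------------------
# pupil construction
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def _pupil_grid(config: OpticalConfig):
    """Cell-centered symmetric (kx, ky) grid spanning the aperture."""
    p = config.pupil_samples
    dk = 2 * config.k_max / p
    kx = (np.arange(p) - (p - 1) / 2.0) * dk
    KX, KY = np.meshgrid(kx, kx, indexing="ij")
    KR = np.hypot(KX, KY)
    inside = KR <= config.k_max
    s = np.where(inside, KR / config.k_medium, 0.0)
    c = np.sqrt(np.clip(1.0 - s * s, 0.0, None))
    phi = np.arctan2(KY, KX)
    kz = config.k_medium * c
    return kx, dk, KX, KY, inside, s, c, phi, kz


def _beam_amplitude(config: OpticalConfig, KX, KY, inside):
    """Beam amplitude over the pupil, clipped by the aperture."""
    ap_r = config.aperture_diameter_mm / 2.0
    r_mm = np.hypot(KX, KY) / _kmax_safe(config) * ap_r
    beam_r = config.beam_diameter_mm / 2.0
    if config.beam_profile == "flat":
        amp = np.where(r_mm <= beam_r, 1.0, 0.0)
    else:  # gaussian, 1/e^2 intensity radius = beam radius
        amp = np.exp(-((r_mm / beam_r) ** 2))
    return np.where(inside, amp, 0.0)


def _kmax_safe(config: OpticalConfig) -> float:
    return config.k_max


def _mask_modulation(config: OpticalConfig, mask: PhaseMask, eom_phase: float,
                     KX, KY, inside):
    """Complex pupil modulation of the mask and the on-region map."""
    kmax = config.k_max
    if mask.kind == "flat":
        on = np.zeros_like(inside)
        return np.exp(1j * eom_phase * on), on  # identity; eom phase global/no-op
    if mask.kind == "bisected_x":
        on = inside & (KX < 0)
        return np.where(on, np.exp(1j * eom_phase), 1.0 + 0j), on
    if mask.kind == "bisected_y":
        on = inside & (KY < 0)
        return np.where(on, np.exp(1j * eom_phase), 1.0 + 0j), on
    if mask.kind == "tophat":
        on = inside & (np.hypot(KX, KY) <= mask.tophat_radius_fraction * kmax)
        return np.where(on, np.exp(1j * eom_phase), 1.0 + 0j), on
    if mask.kind == "vortex":
        on = np.zeros_like(inside)
        return np.exp(1j * (np.arctan2(KY, KX) + eom_phase)), on
    if mask.kind == "two_beam":
        ap_r = config.aperture_diameter_mm / 2.0
        x_mm = KX / kmax * ap_r
        y_mm = KY / kmax * ap_r
        w = mask.two_beam_diameter_mm / 2.0
        off = mask.two_beam_offset_mm
        g1 = np.exp(-(((x_mm - off) ** 2 + y_mm**2) / w**2))
        g2 = np.exp(-(((x_mm + off) ** 2 + y_mm**2) / w**2))
        rel = mask.two_beam_relative_phase + (eom_phase - math.pi)
        on = inside & (x_mm < 0)
        # amplitude replacement: the two offset Gaussian beams
        return np.where(inside, g1 + g2 * np.exp(1j * rel), 0.0), on
    raise ValueError(f"unsupported mask {mask.kind!r}")


@dataclasses.dataclass
class PupilField:
    """Vectorial pupil samples ready for focusing.

    g has shape (3, P, P): the x, y, z focal-field integrands including beam
    amplitude, mask modulation, EOM phase, apodization and the high-NA
    polarization rotation.
    """

    config: OpticalConfig
    mask: PhaseMask
    polarization: Polarization
    eom_phase: float
    g: np.ndarray
    kx: np.ndarray
    dk: float
    kz: np.ndarray
    on_region: np.ndarray

    @property
    def total_power(self) -> float:
        """Integrated focal-plane intensity via Parseval; z-invariant."""
        return float((2 * np.pi / self.dk) ** 2 * np.sum(np.abs(self.g) ** 2))


def build_pupil(
    config: OpticalConfig,
    mask: PhaseMask,
    polarization: Optional[Polarization] = None,
    eom_phase: float = math.pi,
) -> PupilField:
    """Assemble the vectorial pupil for a mask, polarization and EOM phase."""
    if polarization is None:
        polarization = default_polarization(mask.kind)
    if mask.kind == "two_beam" and config.beam_profile == "flat":
        # the two-beam mask carries its own Gaussian amplitudes
        pass
    kx, dk, KX, KY, inside, s, c, phi, kz = _pupil_grid(config)
    amp = _beam_amplitude(config, KX, KY, inside)
    mod, on = _mask_modulation(config, mask, eom_phase, KX, KY, inside)
    if mask.kind == "two_beam":
        base = np.where(inside, mod, 0.0)  # modulation includes amplitude
    else:
        base = amp * mod
    # aplanatic apodization sqrt(cos) and the dkx dky / cos Jacobian
    base = np.where(inside, base / np.sqrt(np.where(inside, c, 1.0)), 0.0)

    px, py = polarization.jones()
    cphi, sphi = np.cos(phi), np.sin(phi)
    g = np.empty((3,) + base.shape, dtype=complex)
    g[0] = base * (px * (c * cphi**2 + sphi**2) + py * (c - 1.0) * sphi * cphi)
    g[1] = base * (px * (c - 1.0) * sphi * cphi + py * (c * sphi**2 + cphi**2))
    g[2] = base * (-s * (px * cphi + py * sphi))
    g[:, ~inside] = 0.0
    return PupilField(config, mask, polarization, float(eom_phase),
                      g, kx, dk, kz, on)


# ---------------------------------------------------------------------------
# focusing (chirp-z evaluation of the Debye sum)
# ---------------------------------------------------------------------------

def _czt_axis(g: np.ndarray, pts: np.ndarray, dk: float, axis: int) -> np.ndarray:
    """Evaluate sum_n g[n] exp(i kx_n p) for equally spaced points p."""
    if len(pts) == 1:
        # same k-origin convention as the czt branch (k_n = n dk); the caller
        # applies the common k0 phase correction afterwards
        k = np.arange(g.shape[axis]) * dk
        ph = np.exp(1j * k * pts[0])
        return np.tensordot(g, ph, axes=([axis], [0]))[..., None].swapaxes(-1, axis)
    d = pts[1] - pts[0]
    out = czt(g, len(pts), np.exp(1j * dk * d), np.exp(-1j * dk * pts[0]), axis=axis)
    return out


def focus_field(
    pupil: PupilField,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
) -> np.ndarray:
    """Three-component complex focal field on the separable grid x × y × z (nm).

    x, y, z must be equally spaced (length-1 arrays allowed).  Returns an
    array of shape (3, len(x), len(y), len(z)).  The axial propagator is
    exp(-i kz z), which orients z so that increasing the EOM phase beyond pi
    moves the top-hat minimum toward positive z.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    for arr, name in ((x, "x"), (y, "y"), (z, "z")):
        if len(arr) > 2 and not np.allclose(np.diff(arr), arr[1] - arr[0]):
            raise ValueError(f"{name} must be equally spaced")
    out = np.empty((3, len(x), len(y), len(z)), dtype=complex)
    # account for kx offset of the cell-centered grid: kx[0] = -(P-1)/2 * dk
    for iz, zv in enumerate(z):
        gz = pupil.g * np.exp(-1j * pupil.kz * zv)
        t = _czt_axis(gz, x, pupil.dk, axis=1)
        t = _czt_axis(t, y, pupil.dk, axis=2)
        # _czt_axis assumes the k grid starts at index 0 with value k0:
        out[:, :, :, iz] = t
    # phase correction for k0 = kx[0] (czt uses exp(i n dk p); actual k = k0 + n dk)
    k0 = pupil.kx[0]
    out *= np.exp(1j * k0 * x)[None, :, None, None]
    out *= np.exp(1j * k0 * y)[None, None, :, None]
    return out


@functools.lru_cache(maxsize=8)
def airy_peak(config: OpticalConfig) -> float:
    """Raw on-axis intensity of the flat-phase reference PSF (Airy peak).

    The peak at the origin is independent of the (uniform) polarization, so a
    single value serves every mask of the same configuration.
    """
    pupil = build_pupil(config, PhaseMask.flat(), Polarization("linear", 0.0), 0.0)
    e0 = pupil.g.sum(axis=(1, 2))
    return float(np.sum(np.abs(e0) ** 2))


@functools.lru_cache(maxsize=8)
def _flat_total_power(config: OpticalConfig) -> float:
    pupil = build_pupil(config, PhaseMask.flat(), Polarization("linear", 0.0), 0.0)
    return pupil.total_power


@dataclasses.dataclass
class PSFStack:
    """Normalized 3D intensity with its axes and normalization metadata.

    data[i, j, k] is the intensity at (x[i], y[j], z[k]) in units of the
    Airy reference peak I_A(0) at equal total power, so the flat-phase
    reference PSF has maximum 1.
    """

    data: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    voxel_size_nm: float
    meta: dict = dataclasses.field(default_factory=dict)

    def axis_points(self, axis: str) -> np.ndarray:
        return {"x": self.x, "y": self.y, "z": self.z}[axis]

    def axis_profile(self, axis: str) -> np.ndarray:
        """1D intensity profile along `axis` through the center of the others."""
        ax = "xyz".index(axis)
        idx = [s // 2 for s in self.data.shape]
        sl = list(idx)
        sl[ax] = slice(None)
        return self.data[tuple(sl)]

    @property
    def center_value(self) -> float:
        return float(self.data[tuple(s // 2 for s in self.data.shape)])


def compute_psf(
    pupil: PupilField,
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    shape: Optional[Tuple[int, int, int]] = None,
    voxel_size_nm: Optional[float] = None,
    warn_small_grid: bool = True,
) -> PSFStack:
    """Normalized intensity stack around `center` (nm).

    Normalization: divide by total power (equal-summed-intensity convention),
    then scale so the flat-phase reference peak is 1.  A diagnostic warning
    is raised when the lateral window cannot contain the first Airy ring
    (suppress with warn_small_grid=False for deliberate minimum-region
    windows).
    """
    cfg = pupil.config
    shape = shape or cfg.grid_shape
    voxel = voxel_size_nm if voxel_size_nm is not None else cfg.voxel_size_nm
    axes = [
        c + (np.arange(n) - (n - 1) / 2.0) * voxel
        for c, n in zip(center, shape)
    ]
    airy_radius = 0.61 * cfg.wavelength_nm / cfg.numerical_aperture
    if (warn_small_grid and len(axes[0]) > 1
            and (len(axes[0]) - 1) * voxel / 2.0 < airy_radius):
        warnings.warn(
            "lateral grid extent below the first Airy ring radius "
            f"({airy_radius:.0f} nm); the stack may clip the PSF core",
            stacklevel=2,
        )
    fields = focus_field(pupil, *axes)
    intensity = np.sum(np.abs(fields) ** 2, axis=0)
    scale = _flat_total_power(cfg) / pupil.total_power / airy_peak(cfg)
    data = intensity * scale
    meta = {
        "mask": pupil.mask.kind,
        "eom_phase_rad": pupil.eom_phase,
        "polarization": (pupil.polarization.kind, pupil.polarization.angle),
        "total_power": pupil.total_power,
        "airy_reference_max": airy_peak(cfg),
        "center_nm": tuple(float(c) for c in center),
    }
    return PSFStack(data, axes[0], axes[1], axes[2], voxel, meta)


# ---------------------------------------------------------------------------
# minima, displacement slopes, contrast
# ---------------------------------------------------------------------------

def _parabolic_vertex(xm, x0, xp, fm, f0, fp):
    """Vertex of the parabola through three equally spaced points."""
    denom = fm - 2.0 * f0 + fp
    if denom <= 0:
        return x0, f0  # flat or maximum: fall back to the discrete minimum
    delta = 0.5 * (fm - fp) / denom
    xv = x0 + delta * (xp - x0)
    fv = f0 - 0.25 * (fm - fp) * delta
    return xv, fv


def _profile_minimum(pts: np.ndarray, prof: np.ndarray):
    i = int(np.argmin(prof))
    if i == 0 or i == len(prof) - 1:
        raise MinimumOnBoundaryError(
            "intensity minimum on the grid boundary; enlarge the scan window"
        )
    return _parabolic_vertex(pts[i - 1], pts[i], pts[i + 1],
                             prof[i - 1], prof[i], prof[i + 1])


def minimum_position(psf: PSFStack, axis: str) -> float:
    """Sub-voxel position (nm) of the intensity minimum along `axis`.

    Uses the 1D profile through the grid center of the other axes and a
    3-point parabolic interpolation around the discrete minimum.
    """
    pos, _ = _profile_minimum(psf.axis_points(axis), psf.axis_profile(axis))
    return float(pos)


def minimum_value(psf: PSFStack, axis: str) -> float:
    """Sub-voxel interpolated intensity at the minimum along `axis`."""
    _, val = _profile_minimum(psf.axis_points(axis), psf.axis_profile(axis))
    return float(max(val, 0.0))


def _line_stack(config, mask, axis, eom_phase, extent_nm, voxel=None,
                polarization=None) -> PSFStack:
    """PSF sampled along a single line through the origin (cheap scan probe)."""
    voxel = voxel if voxel is not None else config.voxel_size_nm
    n = 2 * int(math.ceil(extent_nm / voxel)) + 1
    shape = [1, 1, 1]
    shape["xyz".index(axis)] = n
    pupil = build_pupil(config, mask, polarization, eom_phase)
    return compute_psf(pupil, shape=tuple(shape), voxel_size_nm=voxel,
                       warn_small_grid=False)


@functools.lru_cache(maxsize=32)
def phase_to_displacement(
    config: OpticalConfig,
    mask: PhaseMask,
    axis: Optional[str] = None,
    phase_window_deg: float = 20.0,
    n_phases: int = 8,
) -> float:
    """Displacement of the intensity minimum per degree of EOM phase (nm/deg).

    Simulates the PSF at EOM phases pi +/- {5, 10, 15, 20} degrees (for the
    default window), locates the sub-voxel minimum along the mask's scan
    axis, and fits a line through displacement vs phase.  Positive slope by
    the package's axis conventions.
    """
    if axis is None:
        axis = mask.scan_axis
    if axis is None:
        raise ValueError(f"mask {mask.kind!r} has no EOM scan axis")
    if mask.scan_axis != axis:
        raise ValueError(f"mask {mask.kind!r} scans {mask.scan_axis!r}, not {axis!r}")
    half = np.linspace(phase_window_deg / (n_phases // 2), phase_window_deg,
                       n_phases // 2)
    offsets = np.r_[-half[::-1], half]  # default: +/- {5, 10, 15, 20} degrees
    # generous window: expect at most ~5 nm/deg
    extent = max(60.0, 5.0 * phase_window_deg)
    disp = []
    for off in offsets:
        stack = _line_stack(config, mask, axis, math.pi + math.radians(off), extent)
        disp.append(minimum_position(stack, axis))
    disp = np.asarray(disp)
    order = np.argsort(offsets)
    if not np.all(np.diff(disp[order]) > 0) and not np.all(np.diff(disp[order]) < 0):
        raise ValueError("minimum displacement not monotonic over the phase window")
    slope = float(np.polyfit(offsets, disp, 1)[0])
    return slope


def contrast(psf: PSFStack, axis: Optional[str] = None) -> float:
    """PSF minimum relative to the Airy reference maximum (I_A(0) units).

    With `axis` given, the sub-voxel minimum of the profile along that axis
    through the center is used; otherwise the center voxel value (the
    pattern minimum for symmetric patterns at EOM phase pi, and the
    reference maximum itself for the degenerate flat mask).
    """
    if axis is None:
        return psf.center_value
    return minimum_value(psf, axis)


def scan_quality_curves(
    config: OpticalConfig,
    mask: PhaseMask,
    axis: Optional[str] = None,
    displacements_nm: Sequence[float] = (0.0, 100.0, 200.0, 300.0, 400.0),
    polarization: Optional[Polarization] = None,
):
    """Contrast and minimum steepness while scanning the minimum via the EOM.

    For each requested displacement the minimum is placed at that position
    by scanning the EOM phase around the nominal value from the fitted
    phase-to-displacement slope and minimizing the intensity seen at the
    displaced position (the pinhole-and-phase-ramp reading, which stays
    defined even where PSF asymmetry washes out the local minimum).  The
    table reports the displacement, the contrast (minimum intensity over
    I_A(0)) and the local quadratic steepness of the intensity along the
    scan axis at that position (nm^-2).  Displacements outside the
    phase-periodic scan range are dropped with a warning.
    """
    import pandas as pd

    if axis is None:
        axis = mask.scan_axis
    if polarization is None:
        polarization = default_polarization(mask.kind)
    slope = phase_to_displacement(config, mask, axis)
    period_nm = abs(slope) * 360.0
    ia = "xyz".index(axis)
    voxel = config.voxel_size_nm
    rows = []
    for d in displacements_nm:
        if abs(d) > period_nm:
            warnings.warn(f"displacement {d} nm beyond one phase period "
                          f"(+/-{period_nm:.0f} nm); truncated", stacklevel=2)
            continue
        nominal = math.pi + math.radians(d / slope)
        scan = nominal + np.radians(np.linspace(-30.0, 30.0, 13))
        point = [np.array([0.0])] * 3
        point[ia] = np.array([d - voxel, d, d + voxel])
        vals = []
        for ph in scan:
            pupil = build_pupil(config, mask, polarization, ph)
            f = focus_field(pupil, *point)
            inten = np.sum(np.abs(f) ** 2, axis=0).ravel()
            scale = _flat_total_power(config) / pupil.total_power / airy_peak(config)
            vals.append(inten * scale)
        vals = np.asarray(vals)  # (n_phases, 3)
        center_trace = vals[:, 1]
        i = int(np.argmin(center_trace))
        if 0 < i < len(scan) - 1:
            _, cmin = _parabolic_vertex(scan[i - 1], scan[i], scan[i + 1],
                                        center_trace[i - 1], center_trace[i],
                                        center_trace[i + 1])
        else:
            cmin = center_trace[i]
        steep = (vals[i, 0] - 2 * vals[i, 1] + vals[i, 2]) / voxel**2
        rows.append({"displacement_nm": float(d),
                     "contrast": float(max(cmin, 0.0)),
                     "steepness": float(steep)})
    return pd.DataFrame(rows)
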