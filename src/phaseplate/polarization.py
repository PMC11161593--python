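"""Jones-calculus model of the variable phase plate.

The phase plate is a chain of polarization optics: an electro-optical
modulator (EOM, a variable retarder with vertical axis), an optional
compensation half-wave plate (HWP), a binary spatial light modulator whose
'on'-pixels act as a half-wave plate at (ideally) 45 degrees, and a
polarizer transmitting horizontal polarization.  A beam polarized at 45
degrees enters the chain; after the polarizer the 'on'-pixel light carries
the EOM phase phi while the 'off'-pixel light carries none, so the two
interfere in the focus with intensity E0^2 (1 + cos(phi - xi)).

All angles are radians internally (degrees only at user interfaces) and
measured counterclockwise from the horizontal axis.  Global phases are
dropped throughout; only intensities are contractual.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence, Union

import numpy as np
from scipy import optimize

__all__ = [
    "PolarizationState",
    "RetarderElement",
    "PolarizerElement",
    "SLMImperfection",
    "CompensationResult",
    "retarder_matrix",
    "polarizer_matrix",
    "propagate",
    "interference_intensity",
    "on_off_residual",
    "compensate_slm",
    "max_rotation_angle",
    "polarization_deviation",
    "E_45",
]


@dataclasses.dataclass(frozen=True)
class PolarizationState:
    """Jones vector (e_h, e_v) in the horizontal/vertical coordinate system."""

    e_h: complex
    e_v: complex

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e_h) and np.isfinite(self.e_v)):
            raise ValueError("polarization components must be finite")

    @property
    def intensity(self) -> float:
        """Squared norm; invariant under a global phase."""
        return abs(self.e_h) ** 2 + abs(self.e_v) ** 2

    def as_array(self) -> np.ndarray:
        return np.array([self.e_h, self.e_v], dtype=complex)

    @classmethod
    def from_array(cls, v: np.ndarray) -> "PolarizationState":
        return cls(complex(v[0]), complex(v[1]))

    @classmethod
    def linear(cls, angle: float, amplitude: float = 1.0) -> "PolarizationState":
        """Linear polarization at `angle` radians from horizontal."""
        return cls(amplitude * math.cos(angle), amplitude * math.sin(angle))


#: the 45-degree input state with unit intensity (E0 = 1)
E_45 = PolarizationState.linear(math.pi / 4)


@dataclasses.dataclass(frozen=True)
class RetarderElement:
    """Waveplate with phase delay `phase_delay` and fast axis at `axis_angle`.

    phase_delay = pi with axis at 45 degrees models an ideal SLM 'on'-pixel
    or a HWP; axis_angle = 0 with a variable delay models the EOM.
    """

    phase_delay: float
    axis_angle: float = 0.0


@dataclasses.dataclass(frozen=True)
class PolarizerElement:
    """Ideal linear polarizer; default transmission axis horizontal."""

    transmission_axis: float = 0.0


Element = Union[RetarderElement, PolarizerElement]


def retarder_matrix(element: RetarderElement) -> np.ndarray:
    """2x2 Jones matrix W(phi, alpha) of a retarder.

    W = [[cos^2 a + e^{i phi} sin^2 a,   (1 - e^{i phi}) cos a sin a],
         [(1 - e^{i phi}) cos a sin a,   sin^2 a + e^{i phi} cos^2 a]]

    Unitary (lossless); diagonal at alpha = 0, where it reduces to
    diag(1, e^{i phi}) -- the EOM matrix.
    """
    return _retarder_matrix(element.phase_delay, element.axis_angle)


def _retarder_matrix(phase_delay, axis_angle) -> np.ndarray:
    """Broadcasting form: inputs may be arrays; returns (..., 2, 2)."""
    phase_delay = np.asarray(phase_delay, dtype=float)
    axis_angle = np.asarray(axis_angle, dtype=float)
    e = np.exp(1j * phase_delay)
    c, s = np.cos(axis_angle), np.sin(axis_angle)
    w = np.empty(np.broadcast(phase_delay, axis_angle).shape + (2, 2), dtype=complex)
    w[..., 0, 0] = c * c + e * s * s
    w[..., 0, 1] = (1.0 - e) * c * s
    w[..., 1, 0] = w[..., 0, 1]
    w[..., 1, 1] = s * s + e * c * c
    return w


def polarizer_matrix(element: PolarizerElement) -> np.ndarray:
    """Idempotent projector onto the transmission axis."""
    c, s = math.cos(element.transmission_axis), math.sin(element.transmission_axis)
    return np.array([[c * c, c * s], [c * s, s * s]], dtype=complex)


def element_matrix(element: Element) -> np.ndarray:
    if isinstance(element, RetarderElement):
        return retarder_matrix(element)
    if isinstance(element, PolarizerElement):
        return polarizer_matrix(element)
    raise TypeError(f"unsupported chain element: {element!r}")


def propagate(chain: Sequence[Element], state: PolarizationState) -> PolarizationState:
    """Send `state` through `chain` (listed in the order the beam meets it)."""
    if len(chain) == 0:
        raise ValueError("chain must contain at least one element")
    v = state.as_array()
    for element in chain:
        v = element_matrix(element) @ v
    return PolarizationState.from_array(v)


def interference_intensity(phi, xi, e0: float = 1.0):
    """Two-path interference law I = E0^2 (1 + cos(phi - xi)).

    phi is the EOM phase on the 'on'-pixel path, xi the position-dependent
    extra phase of the focal field.  Zero iff phi - xi = pi (mod 2 pi).
    """
    return e0**2 * (1.0 + np.cos(np.asarray(phi) - np.asarray(xi)))


@dataclasses.dataclass(frozen=True)
class SLMImperfection:
    """Deviation of the SLM 'on'-pixels from an ideal HWP at 45 degrees.

    delta_phase: retardance deviation from pi (rad).
    delta_axis: axis deviation from 45 degrees (rad); the FLCoS device
        modelled in this package has its axis at 33.5 degrees, i.e.
        delta_axis = -11.5 degrees.
    """

    delta_phase: float = 0.0
    delta_axis: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.delta_phase) >= math.pi / 2:
            raise ValueError("delta_phase outside model validity (|dphi| < pi/2)")
        if abs(self.delta_axis) >= math.pi / 4:
            raise ValueError("delta_axis outside model validity (|dalpha| < pi/4)")


@dataclasses.dataclass(frozen=True)
class CompensationResult:
    hwp_angle: float          # compensation HWP axis angle (rad)
    eom_offset: float         # static EOM phase at the interference minimum (rad)
    residual_intensity: float # min |E_on + E_off|^2 after the polarizer, per unit input
    converged: bool           # residual below the requested tolerance


def on_off_residual(imperfection: SLMImperfection, hwp_angle, eom_phase):
    """Summed on+off field intensity after the polarizer, unit input intensity.

    Chain: 45-degree input -> EOM(eom_phase) -> HWP(pi, hwp_angle) ->
    SLM on-pixels W(pi + dphi, pi/4 + dalpha) (off-pixels: identity) ->
    horizontal polarizer.  The on- and off-pixel fields are summed before
    taking the intensity, modelling destructive interference in the focus.
    Broadcasts over `hwp_angle` and `eom_phase`.
    """
    hwp_angle = np.asarray(hwp_angle, dtype=float)
    eom_phase = np.asarray(eom_phase, dtype=float)
    shape = np.broadcast(hwp_angle, eom_phase).shape
    e45 = E_45.as_array()
    w_eom = _retarder_matrix(eom_phase, 0.0)
    w_hwp = _retarder_matrix(np.pi, hwp_angle)
    w_slm = _retarder_matrix(
        np.pi + imperfection.delta_phase, np.pi / 4 + imperfection.delta_axis
    )
    pre = np.einsum("...ij,...jk,k->...i", w_hwp, w_eom, e45)
    e_on = np.einsum("ij,...j->...i", w_slm, pre)
    # horizontal polarizer keeps only the h components; sum fields, then square
    total = e_on[..., 0] + pre[..., 0]
    res = np.abs(total) ** 2
    return res.reshape(shape) if shape else float(res)


def compensate_slm(
    imperfection: SLMImperfection,
    tolerance: float = 1e-9,
    coarse: int = 180,
) -> CompensationResult:
    """Find the HWP angle and EOM phase that null the on+off interference.

    Coarse grid scan (default 1-degree steps) over alpha in [0, pi) x
    phi in [0, 2 pi) followed by Nelder-Mead refinement; the smooth
    two-parameter landscape makes the coarse scan a reliable bracket for
    the global minimum.  A residual above `tolerance` is reported in the
    result (converged=False), not raised, so callers can map residual
    landscapes.

    For an ideal SLM the minimum is degenerate along a curve; the grid point
    nearest the ideal configuration (HWP at 45 degrees, EOM offset pi) is
    chosen so the ideal case reproduces eom_offset = pi.
    """
    alphas = np.linspace(0.0, np.pi, coarse, endpoint=False)
    phis = np.linspace(0.0, 2 * np.pi, 2 * coarse, endpoint=False)
    res = on_off_residual(imperfection, alphas[:, None], phis[None, :])
    # deterministic tie-break among numerically equal minima
    tie = 1e-15 * ((alphas[:, None] - np.pi / 4) ** 2 + (phis[None, :] - np.pi) ** 2)
    i, j = np.unravel_index(np.argmin(res + tie), res.shape)
    if res[i, j] <= 1e-18:
        # coarse point already sits on the (possibly degenerate) zero; keep
        # the conventional solution instead of wandering along the valley
        return CompensationResult(
            hwp_angle=float(alphas[i] % np.pi),
            eom_offset=float(phis[j] % (2 * np.pi)),
            residual_intensity=float(res[i, j]),
            converged=res[i, j] < tolerance,
        )

    def objective(x):
        return on_off_residual(imperfection, x[0], x[1])

    opt = optimize.minimize(
        objective,
        x0=np.array([alphas[i], phis[j]]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-22, "maxiter": 4000},
    )
    alpha, phi = opt.x
    residual = float(opt.fun)
    return CompensationResult(
        hwp_angle=float(alpha % np.pi),
        eom_offset=float(phi % (2 * np.pi)),
        residual_intensity=residual,
        converged=residual < tolerance,
    )


def max_rotation_angle(axis_angle: float) -> float:
    """Largest rotation of a linear input by a pi retarder with axis at `axis_angle`.

    A half-wave plate reflects the polarization direction about its axis, so a
    linear state can be rotated by at most 2 * axis_angle.  The FLCoS SLM axis
    at 33.5 degrees therefore rotates by at most 67 degrees.
    """
    if not 0.0 <= axis_angle <= math.pi / 2:
        raise ValueError("axis_angle must be in [0, pi/2]")
    return 2.0 * axis_angle


def polarization_deviation(axis_angle: float) -> float:
    """Best-case deviation from the optimal polarizations of the x and y patterns.

    The bisected x and y patterns need mutually orthogonal linear
    polarizations.  With a double reflection off an SLM whose axis sits at
    `axis_angle` the beam can be rotated by at most 2*axis_angle, so splitting
    the shortfall symmetrically leaves a deviation of (pi/2 - 2*axis_angle)/2
    for each pattern: 11.5 degrees for the 33.5-degree FLCoS axis.
    """
    if not 0.0 <= axis_angle <= math.pi / 4:
        raise ValueError("axis_angle must be in [0, pi/4]")
    return (math.pi / 2 - 2.0 * axis_angle) / 2.0
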