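"""Configuration files, array/table export and fixture generation.

Units are explicit in every config key (nm for focal space, mm for pupil
space, degrees in user-facing files; radians internally).  PSF stacks are
exported as multi-page TIFF with a JSON sidecar carrying the normalization
constants; tables are CSV with documented headers; run logs are JSON lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from . import crb as _crb
from .psf import OpticalConfig, PhaseMask, Polarization, PSFStack

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "save_psf",
    "load_psf",
    "generate_fixtures",
    "log_jsonl",
    "parabolic_probe_model",
]

_OPTICAL_KEYS = {
    "numerical_aperture": "numerical_aperture",
    "refractive_index": "refractive_index",
    "wavelength_nm": "wavelength_nm",
    "aperture_diameter_mm": "aperture_diameter_mm",
    "beam_diameter_mm": "beam_diameter_mm",
    "beam_profile": "beam_profile",
    "voxel_size_nm": "voxel_size_nm",
    "pupil_samples": "pupil_samples",
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated, unit-explicit run description that round-trips via YAML."""

    optical: OpticalConfig = OpticalConfig()
    mask_kind: str = "bisected_x"
    tophat_radius_fraction: float = 1.0 / math.sqrt(2.0)
    polarization: str = "default"  # "default" | "circular" | "linear:<deg>"
    eom_phase_deg: float = 180.0
    background_b: float = 0.005
    scan_L_nm: float = 50.0
    scan_Lz_nm: float = 150.0
    seed: int = 1
    verbosity: int = 1

    def mask(self) -> PhaseMask:
        if self.mask_kind == "tophat":
            return PhaseMask.tophat(self.tophat_radius_fraction)
        return PhaseMask(self.mask_kind)

    def resolve_polarization(self) -> Optional[Polarization]:
        if self.polarization == "default":
            return None
        if self.polarization == "circular":
            return Polarization.circular()
        if self.polarization.startswith("linear:"):
            return Polarization.linear_deg(float(self.polarization.split(":")[1]))
        raise ValueError(f"bad polarization value {self.polarization!r}")


def _as_dict(cfg: RunConfig) -> dict:
    d = {k: getattr(cfg.optical, k) for k in _OPTICAL_KEYS}
    d["grid_shape"] = list(cfg.optical.grid_shape)
    for f in dataclasses.fields(RunConfig):
        if f.name != "optical":
            d[f.name] = getattr(cfg, f.name)
    return d


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_dict(cfg), sort_keys=True))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; defaults fill missing keys.

    Raises ValueError naming the offending key for unknown keys or
    physically invalid values (validation is delegated to the dataclasses).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    optical_kwargs = {}
    run_kwargs = {}
    run_fields = {f.name for f in dataclasses.fields(RunConfig)} - {"optical"}
    for key, value in raw.items():
        if key in _OPTICAL_KEYS:
            optical_kwargs[key] = value
        elif key == "grid_shape":
            optical_kwargs["grid_shape"] = tuple(value)
        elif key in run_fields:
            run_kwargs[key] = value
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    try:
        optical = OpticalConfig(**optical_kwargs)
        cfg = RunConfig(optical=optical, **run_kwargs)
        cfg.mask()
        cfg.resolve_polarization()
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: {err}") from err
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_as_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# array export
# ---------------------------------------------------------------------------

def save_psf(stack: PSFStack, path) -> None:
    """Write a PSF stack as multi-page TIFF (pages along z) + JSON sidecar."""
    path = Path(path)
    # pages along z, rows x, cols y
    pages = np.moveaxis(stack.data, 2, 0).astype(np.float32)
    meta = {
        "axes": "ZXY",
        "voxel_size_nm": stack.voxel_size_nm,
        **{k: v for k, v in stack.meta.items() if _json_ok(v)},
    }
    tifffile.imwrite(path, pages, photometric="minisblack", metadata=meta)
    sidecar = {
        "voxel_size_nm": stack.voxel_size_nm,
        "x_nm": stack.x.tolist(),
        "y_nm": stack.y.tolist(),
        "z_nm": stack.z.tolist(),
        "meta": {k: v for k, v in stack.meta.items() if _json_ok(v)},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def load_psf(path) -> PSFStack:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.moveaxis(pages, 0, 2).astype(float)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PSFStack(
        data,
        np.asarray(sidecar["x_nm"]),
        np.asarray(sidecar["y_nm"]),
        np.asarray(sidecar["z_nm"]),
        sidecar["voxel_size_nm"],
        dict(sidecar.get("meta", {})),
    )


def _json_ok(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def log_jsonl(path, record: dict) -> None:
    """Append a machine-readable run record (config hash, seed, timing...)."""
    record = {"timestamp": time.time(), **record}
    with Path(path).open("a") as fh:
        fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def parabolic_probe_model(
    x: np.ndarray,
    positions_nm=(-25.0, 0.0, 25.0),
    curvature: float = 1e-3,
    floor: float = 0.05,
):
    """Analytic 1D toy probes I_i(x) = a (x - x_i)^2 + c and their exact Fisher.

    Returns (intensities (K, nx), fisher J(x) for N = 1).  The Fisher sum
    uses exact derivatives of p_i = I_i / sum_j I_j, so it serves as a
    closed-form oracle for the finite-difference implementation.
    """
    x = np.asarray(x, dtype=float)
    xi = np.asarray(positions_nm, dtype=float)
    I = curvature * (x[None, :] - xi[:, None]) ** 2 + floor
    S = I.sum(axis=0)
    dI = 2 * curvature * (x[None, :] - xi[:, None])
    dS = dI.sum(axis=0)
    p = I / S
    dp = (dI * S - I * dS) / S**2
    with np.errstate(divide="ignore", invalid="ignore"):
        # J undefined where a probe reaches exactly zero (floor = 0)
        J = (dp**2 / p).sum(axis=0)
    return I, J


def generate_fixtures(out_dir, seed: int = 0) -> dict:
    """Write small deterministic PSF fixtures and a hash manifest.

    Produces reduced-sampling stacks (33^3 voxels at 8 nm, 96 pupil
    samples) for the flat, bisected-x and top-hat masks, plus the analytic
    parabolic 1D probe model with its exact Fisher information.  Rerunning
    with the same seed reproduces identical hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = OpticalConfig(voxel_size_nm=8.0, grid_shape=(33, 33, 33),
                           pupil_samples=96)
    from .psf import build_pupil, compute_psf  # local import to avoid cycles

    manifest = {"seed": seed, "fixtures": []}
    for kind in ("flat", "bisected_x", "tophat"):
        mask = PhaseMask(kind)
        pupil = build_pupil(config, mask)
        stack = compute_psf(pupil, warn_small_grid=False)
        name = f"psf_{kind}.tiff"
        save_psf(stack, out / name)
        manifest["fixtures"].append({
            "file": name,
            "mask": kind,
            "sha256": _sha256(out / name),
            "params": {"voxel_size_nm": 8.0, "shape": [33, 33, 33],
                       "pupil_samples": 96, "eom_phase_rad": math.pi},
        })
    x = np.arange(-40.0, 40.25, 0.5)
    I, J = parabolic_probe_model(x)
    toy = {
        "x_nm": x.tolist(),
        "intensities": I.tolist(),
        "fisher_n1": J.tolist(),
        "crb_center_nm_sqrtN": float(1.0 / math.sqrt(J[len(x) // 2])),
        "params": {"positions_nm": [-25.0, 0.0, 25.0],
                   "curvature": 1e-3, "floor": 0.05},
    }
    (out / "toy_parabolic.json").write_text(json.dumps(toy))
    manifest["fixtures"].append({
        "file": "toy_parabolic.json",
        "sha256": _sha256(out / "toy_parabolic.json"),
        "params": toy["params"],
    })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
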