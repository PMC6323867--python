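"""Synthetic acquisitions emulating the published specimens — no downloads.

Each named fixture builds a ground-truth phantom, acquires a full reflective
rotation series (0.9-degree steps over 360 degrees by default, scaled-down
128-pixel detector), and can write everything to disk: the phantom grids,
per-channel projection stacks with sidecar metadata, ground-truth masks, and
landmark files.  Optional additive Gaussian detector noise is seeded, so a
fixture is byte-identical for a fixed seed.

Fixtures:

* ``sphere`` — one opaque gray sphere; the basic surface-recovery target.
* ``ellipse2d`` — a single opaque ellipse in 2D; the classic illustration of
  reflected-light sinogram formation and rim reconstruction.
* ``resistor`` — a banded cylinder with colored rings on a tan body, imaged
  in three (R, G, B) channels, after the axial-color-code test object.
* ``figurine`` — a two-tone compound solid (body + head) with landmarks, for
  registration and cross-modality overlay demos.
* ``shell6`` — a shell-like object whose angular sectors peak in each of the
  six spectral bands (377/50 … 690/70 nm).
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, replace

import numpy as np

from . import io as osio
from .errors import InvalidArgumentError
from .forward import AcquisitionConfig, Sinogram, acquire_series
from .multichannel import SPECTRAL_BANDS_6, SpectralBand, rgb_bands
from .phantoms import EllipsePrimitive, Phantom, axis_coords, make_opaque_phantom

__all__ = ["FIXTURE_NAMES", "fixture_phantom", "fixture_config", "generate_fixture"]

FIXTURE_NAMES = ("sphere", "ellipse2d", "resistor", "figurine", "shell6")

#: Landmarks used by the registration demos, in normalized coordinates.
_LANDMARKS_NORM = np.array([
    [0.0, 0.0, 0.55],
    [0.35, 0.0, -0.1],
    [-0.35, 0.1, -0.2],
    [0.0, -0.4, 0.0],
    [0.15, 0.3, 0.3],
])


def fixture_phantom(name: str, grid_px: int = 64) -> Phantom:
    """Build the ground-truth phantom of a named fixture."""
    if name == "sphere":
        prim = EllipsePrimitive(center=(0, 0, 0), semi_axes=(0.5, 0.5, 0.5),
                                reflectance=(0.5,))
        return make_opaque_phantom([prim], (grid_px,) * 3, channels=1)
    if name == "ellipse2d":
        prim = EllipsePrimitive(center=(0.05, -0.05), semi_axes=(0.45, 0.65),
                                rotation_deg=15.0, reflectance=(0.4,))
        return make_opaque_phantom([prim], (grid_px,) * 2, channels=1)
    if name == "resistor":
        return _resistor_phantom(grid_px)
    if name == "figurine":
        prims = [
            EllipsePrimitive(center=(0, 0, -0.15), semi_axes=(0.3, 0.3, 0.45),
                             reflectance=(0.2, 0.2, 0.8)),       # blue body
            EllipsePrimitive(center=(0, 0, 0.45), semi_axes=(0.22, 0.22, 0.2),
                             reflectance=(0.8, 0.7, 0.2)),       # yellow head
        ]
        return make_opaque_phantom(prims, (grid_px,) * 3, channels=3)
    if name == "shell6":
        return _shell6_phantom(grid_px)
    raise InvalidArgumentError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def _resistor_phantom(grid_px: int) -> Phantom:
    """Cylinder along z with colored rings: tan body, brown/green/red/gold bands."""
    body = (0.82, 0.62, 0.38)  # (R, G, B) reflectance of the body
    rings = [  # (z_lo, z_hi, rgb) in normalized coordinates
        (0.30, 0.45, (0.45, 0.25, 0.10)),   # brown
        (0.05, 0.20, (0.15, 0.60, 0.15)),   # green
        (-0.20, -0.05, (0.85, 0.12, 0.10)),  # red
        (-0.45, -0.30, (0.80, 0.65, 0.15)),  # gold
    ]
    n = grid_px
    z = axis_coords(n)[:, None, None]
    y = axis_coords(n)[None, :, None]
    x = axis_coords(n)[None, None, :]
    radius = 0.35
    inside = (x ** 2 + y ** 2 <= radius ** 2) & (np.abs(z) <= 0.7)
    inside = np.broadcast_to(inside, (n, n, n))
    reflectance = np.zeros((3, n, n, n))
    for ch in range(3):
        reflectance[ch][inside] = body[ch]
    for z_lo, z_hi, rgb in rings:
        band = inside & (z >= z_lo) & (z <= z_hi)
        for ch in range(3):
            reflectance[ch][band] = rgb[ch]
    transmittance = np.where(inside, 0.0, 1.0)
    return Phantom(opacity=inside.copy(), reflectance=reflectance,
                   transmittance=transmittance)


def _shell6_phantom(grid_px: int) -> Phantom:
    """Spherical shell-like solid whose six azimuthal sectors each peak in one band."""
    n = grid_px
    z = axis_coords(n)[:, None, None]
    y = axis_coords(n)[None, :, None]
    x = axis_coords(n)[None, None, :]
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    inside = np.broadcast_to(r <= 0.6, (n, n, n))
    phi = np.arctan2(np.broadcast_to(y, (n, n, n)), np.broadcast_to(x, (n, n, n)))
    sector = np.floor((phi + np.pi) / (2 * np.pi) * 6).astype(int) % 6
    reflectance = np.zeros((6, n, n, n))
    for ch in range(6):
        reflectance[ch][inside] = np.where(sector[inside] == ch, 0.8, 0.1)
    transmittance = np.where(inside, 0.0, 1.0)
    return Phantom(opacity=inside.copy(), reflectance=reflectance,
                   transmittance=transmittance)


def _bands_for(name: str, n_channels: int) -> tuple[SpectralBand, ...]:
    if name == "shell6":
        return SPECTRAL_BANDS_6
    if n_channels == 3:
        return rgb_bands()
    return (SpectralBand("gray", 550.0, 300.0),)


def fixture_config(name: str, detector_px: int = 128, step_deg: float = 0.9,
                   total_angle_deg: float = 360.0,
                   shading_mode: str = "flat") -> AcquisitionConfig:
    """Acquisition geometry for a fixture: scaled-down detector, full turn."""
    phantom_channels = {"sphere": 1, "ellipse2d": 1, "resistor": 3,
                        "figurine": 3, "shell6": 6}
    if name not in phantom_channels:
        raise InvalidArgumentError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return AcquisitionConfig(total_angle_deg=total_angle_deg, step_deg=step_deg,
                             detector_px=detector_px, shading_mode=shading_mode,
                             channels=_bands_for(name, phantom_channels[name]))


def _landmarks_voxel(grid_px: int) -> np.ndarray:
    return (_LANDMARKS_NORM + 1.0) * grid_px / 2.0 - 0.5


def generate_fixture(name: str, out_dir, seed: int = 0,
                     grid_px: int | None = None, detector_px: int = 128,
                     step_deg: float = 0.9, total_angle_deg: float = 360.0,
                     noise_sigma: float = 0.0,
                     shading_mode: str = "flat") -> dict:
    """Write a complete synthetic acquisition to ``out_dir``.

    Emits the per-channel reflectance grids and opacity mask of the phantom,
    one projection stack per spectral channel (with sidecar metadata), and a
    landmark file.  Gaussian detector noise of ``noise_sigma`` (simulation
    units) is drawn from ``seed``; outputs are deterministic given the
    arguments.  Returns a manifest of the written paths.
    """
    if name not in FIXTURE_NAMES:
        raise InvalidArgumentError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if grid_px is None:
        grid_px = 64 if name != "ellipse2d" else 128
    phantom = fixture_phantom(name, grid_px)
    config = fixture_config(name, detector_px=detector_px, step_deg=step_deg,
                            total_angle_deg=total_angle_deg, shading_mode=shading_mode)
    series = acquire_series(phantom, config, mode="reflective")
    rng = np.random.default_rng(seed)
    manifest: dict = {"name": name, "seed": seed, "paths": {}}
    for ch, sino in enumerate(series):
        if noise_sigma > 0:
            sino = replace(sino, data=sino.data + rng.normal(0.0, noise_sigma,
                                                             sino.data.shape))
        band = sino.channel.name if sino.channel else f"ch{ch}"
        p = osio.save_sinogram(sino, out / f"{name}_proj_{band}.tif")
        manifest["paths"][f"projections_{band}"] = str(p)
    for ch in range(phantom.n_channels):
        p = osio.write_tiff_stack(phantom.reflectance[ch],
                                  out / f"{name}_reflectance_ch{ch}.tif",
                                  metadata={"kind": "phantom-reflectance", "channel": ch})
        manifest["paths"][f"reflectance_ch{ch}"] = str(p)
    p = osio.write_tiff_stack(phantom.opacity.astype(np.uint8) * 255,
                              out / f"{name}_opacity.tif", dtype="uint8",
                              metadata={"kind": "phantom-opacity"}, scale_max=255)
    manifest["paths"]["opacity"] = str(p)
    if phantom.ndim == 3:
        p = osio.write_landmarks(_landmarks_voxel(grid_px), out / f"{name}_landmarks.txt")
        manifest["paths"]["landmarks"] = str(p)
    return manifest
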