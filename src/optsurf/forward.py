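"""Forward projection: transmission line integrals and reflected-light imaging.

Geometry convention (pinned for sinogram reproducibility): the sample rotates
counterclockwise about the vertical ``z`` axis viewed from above, the detector
is fixed, and angle 0 views along ``+x``.  Rays are parallel (orthographic /
telecentric) and spaced by ``r`` along the detector; the detector spans
``[-1, 1]`` in normalized object coordinates by default.  A point on the ray
with detector offset ``s`` and path parameter ``t`` sits, in the sample frame,
at ``(x, y) = (c t + s_ s, -s_ t + c s)`` with ``c = cos θ``, ``s_ = sin θ``.

Transmission mode integrates the attenuation grid along each ray (the Radon
transform).  Reflective mode emulates imaging an opaque object against a
uniformly bright background: a ray that never meets an opaque voxel records
the background level ``B``; otherwise it records the first-hit voxel's
per-channel diffuse reflectance, optionally scaled by Lambert's cosine factor
between the outward surface normal and the reversed ray direction.
Semitransparent mode composites emission front-to-back with per-voxel
transmittance, terminating naturally at opaque material (transmittance 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, ModeMismatchError
from .multichannel import SpectralBand, rgb_bands
from .phantoms import Phantom, axis_coords

__all__ = [
    "AcquisitionConfig",
    "Sinogram",
    "transmission_project",
    "reflective_project",
    "semitransparent_project",
    "acquire_series",
    "surface_normals",
]

_SHADING_MODES = ("flat", "lambertian")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Rotation series geometry and radiometry.

    Defaults follow the published acquisition protocol: a 512x512 detector
    rotated through 360 degrees in 0.9-degree steps (400 projections) against
    a background normalized to 1.0 simulation units.  ``detector_spacing`` is
    the normalized distance ``r`` between adjacent parallel rays; ``None``
    spans the detector across the object cube ``[-1, 1]``.
    """

    total_angle_deg: float = 360.0
    step_deg: float = 0.9
    detector_px: int = 512
    detector_spacing: float | None = None
    background_level: float = 1.0
    shading_mode: str = "flat"
    channels: tuple[SpectralBand, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.step_deg <= self.total_angle_deg):
            raise InvalidArgumentError("require 0 < step_deg <= total_angle_deg")
        if self.detector_px < 16:
            raise InvalidArgumentError("detector_px must be >= 16")
        if self.background_level <= 0:
            raise InvalidArgumentError("background_level must be positive")
        if self.shading_mode not in _SHADING_MODES:
            raise InvalidArgumentError(
                f"unknown shading_mode {self.shading_mode!r}; expected one of {_SHADING_MODES}"
            )

    @property
    def spacing(self) -> float:
        return 2.0 / self.detector_px if self.detector_spacing is None else self.detector_spacing

    @property
    def n_angles(self) -> int:
        n = self.total_angle_deg / self.step_deg
        if abs(n - round(n)) > 1e-9:
            raise InvalidArgumentError(
                f"step_deg {self.step_deg} does not divide total_angle_deg "
                f"{self.total_angle_deg} an integer number of times"
            )
        return int(round(n))

    @property
    def angles_deg(self) -> np.ndarray:
        """Projection angles in ``[0, total_angle_deg)``."""
        return np.arange(self.n_angles) * self.step_deg


@dataclass
class Sinogram:
    """An ordered stack of projections over rotation angles.

    ``data`` is ``(n_angles, n_det)`` in 2D slice mode or
    ``(n_angles, n_rows, n_det)`` in volume mode (rows index the vertical
    axis, increasing with ``z``).
    """

    data: np.ndarray
    angles_deg: np.ndarray
    spacing: float
    background_level: float = 1.0
    channel: SpectralBand | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise InvalidArgumentError("sinogram data must be 2D or 3D")
        if self.data.shape[0] != self.angles_deg.shape[0]:
            raise InvalidArgumentError("first data dimension must match the angle list")
        if self.angles_deg.size > 1 and np.any(np.diff(self.angles_deg) <= 0):
            raise InvalidArgumentError("angles must be strictly increasing")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_det(self) -> int:
        return self.data.shape[-1]


def _detector_offsets(n_det: int, spacing: float) -> np.ndarray:
    """Centered detector bin coordinates."""
    return (np.arange(n_det) + 0.5) * spacing - n_det * spacing / 2.0


def _ray_points(angle_deg: float, offsets: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (x, y) along every ray; returns arrays of shape (n_steps, n_det).

    The path parameter covers [-1.5, 1.5], enough for the unit-cube diagonal.
    """
    t_max = 1.5
    n_steps = int(np.ceil(2 * t_max / step))
    t = -t_max + (np.arange(n_steps) + 0.5) * step
    th = np.deg2rad(angle_deg)
    c, s_ = np.cos(th), np.sin(th)
    x = c * t[:, None] + s_ * offsets[None, :]
    y = -s_ * t[:, None] + c * offsets[None, :]
    direction = np.array([c, -s_])  # d(x,y)/dt, unit length
    return x, y, direction


def _to_index(coord: np.ndarray, n: int) -> np.ndarray:
    """Map a normalized coordinate in [-1, 1] to a fractional array index."""
    return (coord + 1.0) * n / 2.0 - 0.5


def transmission_project(phantom: Phantom, angle_deg: float,
                         n_det: int | None = None,
                         spacing: float | None = None) -> np.ndarray:
    """Line integrals of the attenuation grid along parallel rays.

    Returns ``(n_det,)`` for a 2D phantom or ``(n_z, n_det)`` for a 3D one
    (integrated slice by slice).  Linear in the attenuation grid.
    """
    if phantom.attenuation is None:
        raise ModeMismatchError("transmission projection requires an attenuation grid")
    grid = phantom.attenuation
    n = grid.shape[-1]
    if n_det is None:
        n_det = n
    if spacing is None:
        spacing = 2.0 / n_det
    step = 1.0 / n  # half a pixel in normalized units
    x, y, _ = _ray_points(angle_deg, _detector_offsets(n_det, spacing), step)
    iy = _to_index(y, grid.shape[-2])
    ix = _to_index(x, grid.shape[-1])
    if phantom.ndim == 2:
        vals = ndimage.map_coordinates(grid, [iy, ix], order=1, cval=0.0)
        return vals.sum(axis=0) * step
    out = np.empty((grid.shape[0], n_det))
    for iz in range(grid.shape[0]):
        vals = ndimage.map_coordinates(grid[iz], [iy, ix], order=1, cval=0.0)
        out[iz] = vals.sum(axis=0) * step
    return out


def surface_normals(phantom: Phantom, sigma: float = 1.0) -> np.ndarray:
    """Outward unit surface normals from a Gaussian-smoothed opacity field.

    Raw gradients of a binary mask are degenerate, so the opacity grid is
    smoothed (``sigma`` in voxels) before central differencing.  Returns an
    array of shape ``(ndim, *grid)`` with components ordered ``(x, y[, z])``;
    zero vectors far from any surface.
    """
    if phantom.opacity is None:
        raise ModeMismatchError("normals require an opacity grid")
    smooth = ndimage.gaussian_filter(phantom.opacity.astype(np.float64), sigma)
    grads = np.gradient(smooth)  # index order: (y, x) or (z, y, x)
    # gradient points inward (toward higher opacity); outward normal negates it
    comps = [-grads[-1], -grads[-2]] + ([-grads[-3]] if phantom.ndim == 3 else [])
    n = np.stack(comps)
    norm = np.sqrt((n ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(norm > 1e-12, n / norm, 0.0)
    return n


def _first_hit(phantom: Phantom, angle_deg: float, config: AcquisitionConfig):
    """First opaque voxel met by each detector ray.

    Rays march in half-voxel increments with nearest-voxel opacity lookup.
    Returns ``(hit, idx, direction)`` where ``hit`` is the boolean hit image,
    ``idx`` the tuple of hit-voxel indices (valid where ``hit``), and
    ``direction`` the ray travel direction in the sample frame.
    """
    if phantom.opacity is None:
        raise ModeMismatchError("reflective projection requires an opacity grid")
    opac = phantom.opacity
    n = opac.shape[-1]
    step = 1.0 / n
    offsets = _detector_offsets(config.detector_px, config.spacing)
    x, y, direction = _ray_points(angle_deg, offsets, step)
    iy = np.rint(_to_index(y, opac.shape[-2])).astype(np.intp)
    ix = np.rint(_to_index(x, opac.shape[-1])).astype(np.intp)
    valid = ((iy >= 0) & (iy < opac.shape[-2]) & (ix >= 0) & (ix < opac.shape[-1]))
    iy_c = np.clip(iy, 0, opac.shape[-2] - 1)
    ix_c = np.clip(ix, 0, opac.shape[-1] - 1)
    cols = np.arange(config.detector_px)

    if phantom.ndim == 2:
        samples = valid & opac[iy_c, ix_c]          # (n_steps, n_det)
        hit = samples.any(axis=0)
        first = samples.argmax(axis=0)
        idx = (iy_c[first, cols], ix_c[first, cols])
        return hit, idx, direction

    # volume mode: detector rows sample z with the same spacing as columns
    nz = opac.shape[0]
    z_rows = _detector_offsets(config.detector_px, config.spacing)
    iz = np.rint(_to_index(z_rows, nz)).astype(np.intp)
    row_ok = (iz >= 0) & (iz < nz)
    iz_c = np.clip(iz, 0, nz - 1)
    samples = opac[iz_c[:, None, None], iy_c[None], ix_c[None]]
    samples &= valid[None]
    samples &= row_ok[:, None, None]                # (n_rows, n_steps, n_det)
    hit = samples.any(axis=1)
    first = samples.argmax(axis=1)                  # (n_rows, n_det)
    idx = (np.broadcast_to(iz_c[:, None], first.shape),
           iy_c[first, cols[None, :]], ix_c[first, cols[None, :]])
    return hit, idx, direction


def _shade(phantom: Phantom, idx, direction: np.ndarray,
           config: AcquisitionConfig, normals: np.ndarray | None) -> np.ndarray:
    if config.shading_mode == "flat":
        return 1.0
    if normals is None:
        normals = surface_normals(phantom)
    # Lambert: intensity ∝ cos between outward normal and reversed ray
    d = np.zeros(normals.shape[0])
    d[: direction.shape[0]] = direction  # (x, y[, z=0]) components
    cos = sum(normals[k][idx] * (-d[k]) for k in range(normals.shape[0]))
    return np.clip(cos, 0.0, 1.0)


def reflective_project(phantom: Phantom, angle_deg: float,
                       config: AcquisitionConfig | None = None,
                       channel: int = 0,
                       normals: np.ndarray | None = None) -> np.ndarray:
    """Reflected-light projection of an opaque phantom at one angle.

    Rays that miss every opaque voxel record the background level ``B``;
    others record the first-hit voxel's reflectance in ``channel``, times the
    Lambert cosine factor if ``config.shading_mode == "lambertian"``.
    Values lie in ``[0, B]`` whenever reflectance <= 1 and ``B`` >= 1.
    """
    if config is None:
        config = AcquisitionConfig(detector_px=max(16, phantom.grid_shape[-1]))
    if phantom.reflectance is None:
        raise ModeMismatchError("reflective projection requires a reflectance grid")
    hit, idx, direction = _first_hit(phantom, angle_deg, config)
    rho = phantom.reflectance[channel][idx]
    value = rho * _shade(phantom, idx, direction, config, normals)
    return np.where(hit, value, config.background_level)


def semitransparent_project(phantom: Phantom, angle_deg: float,
                            config: AcquisitionConfig | None = None,
                            channel: int = 0) -> np.ndarray:
    """Front-to-back emission/transmittance compositing along each ray.

    Every voxel the ray enters contributes its reflectance attenuated by the
    product of the transmittances of the voxels in front of it; the
    background ``B`` enters with the residual transmittance of the whole
    path.  Opaque voxels carry transmittance 0, so they contribute their
    reflectance and terminate the ray.  Flat shading only.
    """
    if config is None:
        config = AcquisitionConfig(detector_px=max(16, phantom.grid_shape[-1]))
    if phantom.transmittance is None:
        raise ModeMismatchError("semitransparent projection requires a transmittance grid")
    if phantom.ndim != 2:
        raise InvalidArgumentError("semitransparent compositing is implemented for 2D phantoms")
    trans, refl = phantom.transmittance, phantom.reflectance[channel]
    ny, nx = trans.shape
    step = 1.0 / nx
    offsets = _detector_offsets(config.detector_px, config.spacing)
    x, y, _ = _ray_points(angle_deg, offsets, step)
    iy = np.rint(_to_index(y, ny)).astype(np.intp)
    ix = np.rint(_to_index(x, nx)).astype(np.intp)
    valid = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    iy_c, ix_c = np.clip(iy, 0, ny - 1), np.clip(ix, 0, nx - 1)
    # count each voxel once: keep only samples that enter a new voxel
    flat = iy_c * nx + ix_c
    flat = np.where(valid, flat, -1)
    entered = np.empty_like(valid)
    entered[0] = valid[0]
    entered[1:] = valid[1:] & (flat[1:] != flat[:-1])
    eff_t = np.where(entered, trans[iy_c, ix_c], 1.0)
    eff_rho = np.where(entered, refl[iy_c, ix_c], 0.0)
    t_total = np.cumprod(eff_t, axis=0)
    t_before = np.empty_like(t_total)
    t_before[0] = 1.0
    t_before[1:] = t_total[:-1]
    return (eff_rho * t_before).sum(axis=0) + config.background_level * t_total[-1]


def acquire_series(phantom: Phantom, config: AcquisitionConfig,
                   mode: str = "reflective") -> list[Sinogram]:
    """Acquire one projection per angle per channel; returns one Sinogram per channel.

    Deterministic: identical inputs give bit-identical sinograms.  The angle
    list covers ``[0, total_angle_deg)`` at ``step_deg`` (the division must be
    exact).  In reflective mode the first-hit search runs once per angle and
    is shared across channels.
    """
    angles = config.angles_deg
    bands = list(config.channels) if config.channels else _default_bands(phantom, mode)
    if mode == "transmission":
        proj = [transmission_project(phantom, a, config.detector_px, config.spacing)
                for a in angles]
        return [Sinogram(np.stack(proj), angles, config.spacing,
                         config.background_level, channel=bands[0] if bands else None)]
    if mode == "semitransparent":
        stacks = [np.stack([semitransparent_project(phantom, a, config, ch)
                            for a in angles]) for ch in range(max(1, phantom.n_channels))]
    elif mode == "reflective":
        normals = surface_normals(phantom) if config.shading_mode == "lambertian" else None
        n_ch = max(1, phantom.n_channels)
        per_angle = []
        for a in angles:
            hit, idx, direction = _first_hit(phantom, a, config)
            shade = _shade(phantom, idx, direction, config, normals)
            per_angle.append([
                np.where(hit, phantom.reflectance[ch][idx] * shade, config.background_level)
                for ch in range(n_ch)
            ])
        stacks = [np.stack([pa[ch] for pa in per_angle]) for ch in range(n_ch)]
    else:
        raise InvalidArgumentError(f"unknown acquisition mode {mode!r}")
    return [Sinogram(stacks[ch], angles, config.spacing, config.background_level,
                     channel=bands[ch] if ch < len(bands) else None)
            for ch in range(len(stacks))]


def _default_bands(phantom: Phantom, mode: str) -> list[SpectralBand]:
    n = max(1, phantom.n_channels)
    if mode != "transmission" and n == 3:
        return list(rgb_bands())
    return [SpectralBand(name=f"ch{i}", center_nm=500.0 + 50.0 * i, width_nm=50.0)
            for i in range(n)]
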