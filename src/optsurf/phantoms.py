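"""Ground-truth digital phantoms for projection/reconstruction testing.

Phantoms live in normalized object coordinates: every axis spans ``[-1, 1]``
and a grid of ``N`` voxels places voxel centers at ``-1 + (2 i + 1) / N``.
Physical units attach only through ``voxel_size_um``.  Arrays are indexed
``(y, x)`` in 2D and ``(z, y, x)`` in 3D, with the coordinate increasing with
the index on every axis; ``z`` is the vertical (rotation) axis.

Two families are provided:

* the classical ellipse-superposition head phantom (attenuation-valued, 2D)
  used to validate transmission projection and filtered back projection;
* opaque/semitransparent multi-channel primitives (ellipsoids rasterized in
  painter's order) carrying per-channel diffuse reflectance, used to validate
  the reflected-light pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "EllipsePrimitive",
    "Phantom",
    "SHEPP_LOGAN_STANDARD",
    "SHEPP_LOGAN_MODIFIED",
    "make_shepp_logan",
    "make_opaque_phantom",
    "axis_coords",
]

# Each row: (a, b, x0, y0, phi_deg, intensity) with a the x-semi-axis, b the
# y-semi-axis, phi a counterclockwise rotation.  The "standard" intensities
# are the original published ones (gray range dominated by the skull at 2.0);
# the "modified" variant rescales them for display contrast.  Both circulate
# in the tomography literature; tests pin the standard table.
SHEPP_LOGAN_STANDARD: tuple[tuple[float, float, float, float, float, float], ...] = (
    (0.69, 0.92, 0.0, 0.0, 0.0, 2.0),
    (0.6624, 0.8740, 0.0, -0.0184, 0.0, -0.98),
    (0.11, 0.31, 0.22, 0.0, -18.0, -0.02),
    (0.16, 0.41, -0.22, 0.0, 18.0, -0.02),
    (0.21, 0.25, 0.0, 0.35, 0.0, 0.01),
    (0.046, 0.046, 0.0, 0.1, 0.0, 0.01),
    (0.046, 0.046, 0.0, -0.1, 0.0, 0.01),
    (0.046, 0.023, -0.08, -0.605, 0.0, 0.01),
    (0.023, 0.023, 0.0, -0.606, 0.0, 0.01),
    (0.023, 0.046, 0.06, -0.605, 0.0, 0.01),
)

_MODIFIED_INTENSITIES = (1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1)

SHEPP_LOGAN_MODIFIED: tuple[tuple[float, float, float, float, float, float], ...] = tuple(
    row[:5] + (a,) for row, a in zip(SHEPP_LOGAN_STANDARD, _MODIFIED_INTENSITIES)
)


def axis_coords(n: int) -> np.ndarray:
    """Normalized center coordinates of ``n`` voxels spanning ``[-1, 1]``."""
    return -1.0 + (2.0 * np.arange(n) + 1.0) / n


@dataclass
class EllipsePrimitive:
    """An ellipse (2D) or ellipsoid (3D) building block.

    ``center`` and ``semi_axes`` are given in normalized coordinates as
    ``(x, y)`` or ``(x, y, z)``; ``rotation_deg`` rotates the primitive
    counterclockwise in the x-y plane (about the vertical axis in 3D).
    ``intensity`` is an additive attenuation used in transmission mode;
    ``reflectance`` holds one diffuse reflectance per spectral channel for
    reflective mode.  Non-opaque primitives may carry a per-voxel
    ``transmittance`` for semitransparent compositing.
    """

    center: Sequence[float]
    semi_axes: Sequence[float]
    rotation_deg: float = 0.0
    intensity: float = 0.0
    reflectance: Sequence[float] = ()
    opaque: bool = True
    transmittance: float = 1.0

    def __post_init__(self) -> None:
        if len(self.center) != len(self.semi_axes):
            raise InvalidArgumentError("center and semi_axes must have equal length")
        if len(self.center) not in (2, 3):
            raise InvalidArgumentError("primitives are 2D or 3D")
        if any(a <= 0 for a in self.semi_axes):
            raise InvalidArgumentError("semi-axes must be strictly positive")
        if any(not (0.0 <= r <= 1.0) for r in self.reflectance):
            raise InvalidArgumentError("reflectance values must lie in [0, 1]")
        if not (0.0 <= self.transmittance <= 1.0):
            raise InvalidArgumentError("transmittance must lie in [0, 1]")

    @property
    def ndim(self) -> int:
        return len(self.center)

    def contains(self, *coords: np.ndarray) -> np.ndarray:
        """Boolean point-in-primitive test at the given (x, y[, z]) arrays."""
        if len(coords) != self.ndim:
            raise InvalidArgumentError(
                f"primitive is {self.ndim}D, got {len(coords)} coordinate arrays"
            )
        x = np.asarray(coords[0]) - self.center[0]
        y = np.asarray(coords[1]) - self.center[1]
        phi = np.deg2rad(self.rotation_deg)
        c, s = np.cos(phi), np.sin(phi)
        # rotate the query point into the primitive frame (inverse rotation)
        xr = c * x + s * y
        yr = -s * x + c * y
        q = (xr / self.semi_axes[0]) ** 2 + (yr / self.semi_axes[1]) ** 2
        if self.ndim == 3:
            z = np.asarray(coords[2]) - self.center[2]
            q = q + (z / self.semi_axes[2]) ** 2
        return q <= 1.0


@dataclass
class Phantom:
    """A voxelized ground-truth object.

    Grids are optional by mode: ``attenuation`` supports transmission
    projection, ``opacity``/``reflectance`` support reflective projection, and
    ``transmittance`` supports semitransparent compositing.  All present
    grids share one spatial shape; ``reflectance`` has a leading channel axis.
    """

    voxel_size_um: float = 1.0
    attenuation: np.ndarray | None = None
    opacity: np.ndarray | None = None
    reflectance: np.ndarray | None = None
    transmittance: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = set()
        if self.attenuation is not None:
            self.attenuation = np.asarray(self.attenuation, dtype=np.float64)
            if np.any(self.attenuation < 0):
                raise InvalidArgumentError("attenuation must be nonnegative")
            shapes.add(self.attenuation.shape)
        if self.opacity is not None:
            self.opacity = np.asarray(self.opacity, dtype=bool)
            shapes.add(self.opacity.shape)
        if self.reflectance is not None:
            self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
            if self.reflectance.min(initial=0.0) < 0 or self.reflectance.max(initial=0.0) > 1:
                raise InvalidArgumentError("reflectance must lie in [0, 1]")
            shapes.add(self.reflectance.shape[1:])
        if self.transmittance is not None:
            self.transmittance = np.asarray(self.transmittance, dtype=np.float64)
            if self.transmittance.min() < 0 or self.transmittance.max() > 1:
                raise InvalidArgumentError("transmittance must lie in [0, 1]")
            shapes.add(self.transmittance.shape)
        if len(shapes) > 1:
            raise InvalidArgumentError(f"phantom grids disagree on shape: {shapes}")
        if not shapes:
            raise InvalidArgumentError("phantom needs at least one grid")
        self._shape = shapes.pop()

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self._shape

    @property
    def ndim(self) -> int:
        return len(self._shape)

    @property
    def n_channels(self) -> int:
        return 0 if self.reflectance is None else self.reflectance.shape[0]


def _coord_grids(grid_shape: Sequence[int]) -> tuple[np.ndarray, ...]:
    """(x, y[, z]) broadcastable coordinate arrays for an array-indexed grid."""
    if len(grid_shape) == 2:
        ny, nx = grid_shape
        y = axis_coords(ny)[:, None]
        x = axis_coords(nx)[None, :]
        return x, y
    nz, ny, nx = grid_shape
    z = axis_coords(nz)[:, None, None]
    y = axis_coords(ny)[None, :, None]
    x = axis_coords(nx)[None, None, :]
    return x, y, z


def make_shepp_logan(size_px: int, variant: str = "standard",
                     voxel_size_um: float = 1.0) -> Phantom:
    """Rasterize the classical head phantom as an attenuation grid.

    The ten published ellipses are superposed additively, sampled at pixel
    centers in ``[-1, 1]^2`` — deterministic for a fixed ``size_px``, and
    resolution-independent at any fixed normalized coordinate.  ``variant``
    selects the ``"standard"`` intensity table or the high-contrast
    ``"modified"`` one.
    """
    if size_px < 16:
        raise InvalidArgumentError("size_px must be at least 16")
    try:
        table = {"standard": SHEPP_LOGAN_STANDARD, "modified": SHEPP_LOGAN_MODIFIED}[variant]
    except KeyError:
        raise InvalidArgumentError(f"unknown variant {variant!r}") from None
    x, y = _coord_grids((size_px, size_px))
    img = np.zeros((size_px, size_px))
    for a, b, x0, y0, phi, amp in table:
        prim = EllipsePrimitive(center=(x0, y0), semi_axes=(a, b), rotation_deg=phi)
        img[prim.contains(x, y)] += amp
    # overlap of negative ellipses can undershoot zero by float round-off
    np.clip(img, 0.0, None, out=img)
    return Phantom(attenuation=img, voxel_size_um=voxel_size_um)


def make_opaque_phantom(primitives: Sequence[EllipsePrimitive],
                        grid_shape: Sequence[int],
                        channels: int = 1,
                        voxel_size_um: float = 1.0) -> Phantom:
    """Rasterize primitives into opacity / reflectance / transmittance grids.

    Later primitives overwrite earlier ones where they overlap (painter's
    order).  The opacity grid marks voxels inside any opaque primitive; the
    transmittance grid is 1 outside material, the primitive's value inside
    non-opaque material, and 0 inside opaque material.
    """
    if len(primitives) == 0:
        raise InvalidArgumentError("at least one primitive is required")
    if channels < 1:
        raise InvalidArgumentError("channels must be >= 1")
    grid_shape = tuple(int(n) for n in grid_shape)
    ndim = len(grid_shape)
    for p in primitives:
        if p.ndim != ndim:
            raise InvalidArgumentError("primitive dimensionality must match grid_shape")
        if p.reflectance and len(p.reflectance) != channels:
            raise InvalidArgumentError(
                f"primitive has {len(p.reflectance)} reflectance values, expected {channels}"
            )
    coords = _coord_grids(grid_shape)
    opacity = np.zeros(grid_shape, dtype=bool)
    reflectance = np.zeros((channels,) + grid_shape)
    transmittance = np.ones(grid_shape)
    for p in primitives:
        inside = p.contains(*coords)
        opacity[inside] = p.opaque
        rho = np.asarray(p.reflectance if p.reflectance else [0.0] * channels)
        reflectance[:, inside] = rho[:, None]
        transmittance[inside] = 0.0 if p.opaque else p.transmittance
    return Phantom(opacity=opacity, reflectance=reflectance,
                   transmittance=transmittance, voxel_size_um=voxel_size_um)
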