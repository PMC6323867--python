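"""Spectral bands, background normalization, channel compositing,
landmark-based rigid registration, and ROI spectral profiles.

The radiometric convention throughout is the white-background one: the empty
background is the brightest, spectrally flat structure in every channel, so
scaling each channel to put its background estimate at a common reference
level removes inter-channel gain differences ("automatic white balance").
Alignment between channels or modalities is landmark-driven: matched point
pairs yield a least-squares rigid transform (orthogonal Procrustes with
reflections excluded, i.e. the Kabsch solution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    AlignmentRequiredError,
    DegenerateChannelError,
    InsufficientLandmarksError,
    InvalidArgumentError,
)

__all__ = [
    "SpectralBand",
    "SPECTRAL_BANDS_6",
    "rgb_bands",
    "RigidTransform3D",
    "SpectralProfile",
    "estimate_background",
    "white_balance",
    "compose_rgb",
    "fit_rigid_landmarks",
    "apply_transform",
    "spectral_profile",
]


@dataclass(frozen=True)
class SpectralBand:
    """A named optical bandpass: center wavelength and full width, in nm."""

    name: str
    center_nm: float
    width_nm: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise InvalidArgumentError("width_nm must be positive")


#: The six bandpass filters of the multi-spectral acquisition (center/width nm).
SPECTRAL_BANDS_6: tuple[SpectralBand, ...] = (
    SpectralBand("uv", 377.0, 50.0),
    SpectralBand("violet", 420.0, 40.0),
    SpectralBand("blue", 460.0, 50.0),
    SpectralBand("green", 525.0, 50.0),
    SpectralBand("orange", 600.0, 50.0),
    SpectralBand("red", 690.0, 70.0),
)


def rgb_bands() -> tuple[SpectralBand, SpectralBand, SpectralBand]:
    """Nominal red/green/blue bands for three-filter color imaging."""
    return (SpectralBand("red", 600.0, 100.0),
            SpectralBand("green", 530.0, 80.0),
            SpectralBand("blue", 465.0, 90.0))


@dataclass
class SpectralProfile:
    """Per-band mean/sd intensity over one region, ordered by center_nm."""

    bands: tuple[SpectralBand, ...]
    mean: np.ndarray
    sd: np.ndarray
    region: str = ""

    @property
    def argmax_band(self) -> SpectralBand:
        return self.bands[int(np.argmax(self.mean))]


def _data(obj) -> np.ndarray:
    """Accept bare arrays or wrapper dataclasses carrying a ``.data`` array."""
    if isinstance(obj, np.ndarray):
        return obj.astype(np.float64, copy=False)
    return np.asarray(getattr(obj, "data", obj), dtype=np.float64)


def _rewrap(obj, data: np.ndarray):
    import dataclasses

    if not isinstance(obj, np.ndarray) and dataclasses.is_dataclass(obj):
        return dataclasses.replace(obj, data=data)
    return data


def estimate_background(image_or_volume, border_frac: float = 0.05) -> float:
    """Median intensity over a border frame of fractional width ``border_frac``.

    Robust to the sample occupying the center of the field, which is the
    standard layout for white-background acquisitions.
    """
    if not (0.0 < border_frac < 0.5):
        raise InvalidArgumentError("border_frac must lie in (0, 0.5)")
    arr = _data(image_or_volume)
    border = np.zeros(arr.shape, dtype=bool)
    for ax, n in enumerate(arr.shape):
        w = max(1, int(round(border_frac * n)))
        if 2 * w >= n:
            raise InvalidArgumentError("border frame is degenerate for this shape")
        sl_lo = [slice(None)] * arr.ndim
        sl_hi = [slice(None)] * arr.ndim
        sl_lo[ax] = slice(0, w)
        sl_hi[ax] = slice(n - w, n)
        border[tuple(sl_lo)] = True
        border[tuple(sl_hi)] = True
    return float(np.median(arr[border]))


def white_balance(channels: Sequence, reference_level: float | None = None,
                  border_frac: float = 0.05):
    """Scale each channel so its background estimate equals ``reference_level``.

    The reference defaults to the brightest channel's background ("background
    kept constant" semantics).  Returns ``(balanced_channels, gains)``.
    Idempotent: balancing balanced channels yields unit gains.
    """
    if len(channels) < 1:
        raise InvalidArgumentError("at least one channel required")
    backgrounds = [estimate_background(ch, border_frac) for ch in channels]
    if any(b <= 0 for b in backgrounds):
        raise DegenerateChannelError(f"non-positive background estimate in {backgrounds}")
    ref = max(backgrounds) if reference_level is None else float(reference_level)
    gains = [ref / b for b in backgrounds]
    balanced = [_rewrap(ch, _data(ch) * g) for ch, g in zip(channels, gains)]
    return balanced, gains


def compose_rgb(red, green, blue, clip_max: float | None = None) -> np.ndarray:
    """Stack three channels into a color array with a trailing RGB axis.

    Values are clipped (not rescaled) to ``[0, clip_max]`` so balanced
    radiometry is preserved; ``clip_max`` defaults to the global maximum.
    Inputs must already share one shape — align them first.
    """
    arrs = [_data(c) for c in (red, green, blue)]
    if len({a.shape for a in arrs}) != 1:
        raise AlignmentRequiredError("channel shapes differ; apply_transform first")
    rgb = np.stack(arrs, axis=-1)
    hi = float(rgb.max()) if clip_max is None else float(clip_max)
    return np.clip(rgb, 0.0, hi if hi > 0 else None)


@dataclass
class RigidTransform3D:
    """A proper rigid motion ``p -> R p + t`` on (x, y, z) points in voxel units."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise InvalidArgumentError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise InvalidArgumentError("rotation must be orthonormal to 1e-9")
        if np.linalg.det(self.rotation) < 0:
            raise InvalidArgumentError("rotation must be proper (det +1), not a reflection")

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform3D":
        return RigidTransform3D(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform3D(self.rotation @ other.rotation,
                                self.rotation @ other.translation + self.translation)


def fit_rigid_landmarks(source_points: np.ndarray, target_points: np.ndarray
                        ) -> tuple[RigidTransform3D, np.ndarray]:
    """Least-squares rigid transform mapping source landmarks onto targets.

    Kabsch solution: SVD of the centered cross-covariance, with the smallest
    singular direction sign-corrected so the rotation is proper (det +1, no
    reflection).  Returns the transform and per-landmark residual distances.
    Requires >= 3 non-collinear pairs; collinear configurations leave a
    rotation about the line unconstrained and are rejected.
    """
    src = np.atleast_2d(np.asarray(source_points, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(target_points, dtype=np.float64))
    if src.shape != dst.shape or src.shape[1] != 3:
        raise InvalidArgumentError("point sets must be matching (n, 3) arrays")
    if src.shape[0] < 3:
        raise InsufficientLandmarksError("at least 3 landmark pairs are required")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    a, b = src - cs, dst - cd
    h = a.T @ b
    u, sig, vt = np.linalg.svd(h)
    scale = max(np.linalg.norm(a), 1.0)
    if sig[1] <= 1e-9 * scale * scale:
        raise InsufficientLandmarksError("landmarks are collinear (or coincident)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - r @ cs
    transform = RigidTransform3D(r, t)
    residuals = np.linalg.norm(transform.apply_points(src) - dst, axis=1)
    return transform, residuals


def apply_transform(volume_or_points, transform: RigidTransform3D,
                    fill_value: float = 0.0, order: int = 1):
    """Map points exactly, or resample a volume under the rigid transform.

    Points are ``(n, 3)`` in (x, y, z) voxel units.  Volumes are arrays
    indexed ``(z, y, x)``; the output voxel at transformed position takes the
    linearly interpolated source value, with out-of-field voxels set to
    ``fill_value``.
    """
    obj = volume_or_points
    arr = _data(obj)
    if arr.ndim == 2 and arr.shape[1] == 3 and isinstance(obj, np.ndarray):
        return transform.apply_points(arr)
    if arr.ndim != 3:
        raise InvalidArgumentError("expected (n, 3) points or a 3D volume")
    # index space is (z, y, x): conjugate the inverse rotation by the
    # axis-reversing permutation and feed it to affine_transform
    p = np.eye(3)[::-1]
    r_inv = transform.rotation.T
    matrix = p @ r_inv @ p
    offset = -p @ (r_inv @ transform.translation)
    out = ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                   mode="constant", cval=fill_value)
    return _rewrap(obj, out)


def _roi_mask(shape: tuple[int, ...], roi) -> np.ndarray:
    roi_arr = np.asarray(roi)
    if roi_arr.dtype == bool:
        if roi_arr.shape != shape:
            raise AlignmentRequiredError("ROI mask shape must match the channel shape")
        return roi_arr
    lo, hi = roi  # axis-aligned box, half-open index ranges [lo, hi)
    if len(lo) != len(shape) or len(hi) != len(shape):
        raise InvalidArgumentError("ROI box must give lo/hi per axis")
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))] = True
    return mask


def spectral_profile(channels: Sequence, roi, bands: Sequence[SpectralBand] | None = None,
                     region: str = "", check_balance: bool = True) -> SpectralProfile:
    """Per-band mean and standard deviation over an ROI, ordered by center_nm.

    ``roi`` is a boolean mask or an axis-aligned box ``(lo, hi)`` with
    half-open index ranges.  Channels should be white-balanced first; a
    warning is emitted when their backgrounds disagree by more than 5%.
    """
    if bands is None:
        bands = [getattr(ch, "channel", None) or SpectralBand(f"ch{i}", 500.0 + i, 1.0)
                 for i, ch in enumerate(channels)]
    if len(bands) != len(channels):
        raise InvalidArgumentError("one band per channel required")
    arrs = [_data(ch) for ch in channels]
    if len({a.shape for a in arrs}) != 1:
        raise AlignmentRequiredError("channel shapes differ")
    mask = _roi_mask(arrs[0].shape, roi)
    if not mask.any():
        raise InvalidArgumentError("ROI is empty")
    if check_balance and len(arrs) > 1:
        bgs = np.array([estimate_background(a) for a in arrs])
        if bgs.min() > 0 and (bgs.max() - bgs.min()) / bgs.max() > 0.05:
            warnings.warn("channels look unbalanced; white_balance() first",
                          stacklevel=2)
    order = np.argsort([b.center_nm for b in bands], kind="stable")
    mean = np.array([arrs[i][mask].mean() for i in order])
    sd = np.array([arrs[i][mask].std() for i in order])
    return SpectralProfile(tuple(bands[i] for i in order), mean, sd, region=region)
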