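"""File formats: multipage TIFF stacks with text sidecars, landmark files,
phantom specification files, run configuration, and OBJ mesh export.

Every array travels as a little-endian multipage grayscale TIFF (one page per
slice or per projection angle) next to a JSON sidecar ``<name>.json`` holding
the acquisition/reconstruction metadata (angles, detector spacing, background
level, spectral band, voxel size).  Supported sample dialects are uint8,
uint16, and float32; 8-bit export scales ``[0, B]`` onto ``[0, 255]``.
Landmarks are plain text, one ``x y z`` triple per line in voxel units.
Phantom specifications and run configurations are YAML.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .errors import FormatError, InvalidArgumentError
from .forward import AcquisitionConfig, Sinogram
from .multichannel import SpectralBand
from .phantoms import EllipsePrimitive, Phantom
from .reconstruct import ChannelVolume, ReconSettings

__all__ = [
    "write_tiff_stack",
    "read_tiff_stack",
    "save_sinogram",
    "load_sinogram",
    "save_volume",
    "load_volume",
    "write_landmarks",
    "read_landmarks",
    "load_phantom_spec",
    "save_phantom_spec",
    "RunConfig",
    "load_run_config",
    "export_mesh_obj",
]

_DTYPES = {"uint8": np.uint8, "uint16": np.uint16, "float32": np.float32}


def _sidecar(path: pathlib.Path) -> pathlib.Path:
    return path.with_suffix(path.suffix + ".json")


def write_tiff_stack(data: np.ndarray, path, dtype: str = "float32",
                     metadata: dict | None = None,
                     scale_max: float = 1.0) -> pathlib.Path:
    """Write an array as a multipage little-endian TIFF plus a JSON sidecar.

    Integer dialects map ``[0, scale_max]`` onto the full dtype range
    (value ``scale_max`` -> 255 for uint8); float32 is written verbatim.
    """
    path = pathlib.Path(path)
    if dtype not in _DTYPES:
        raise FormatError(f"unsupported dialect {dtype!r}; use one of {sorted(_DTYPES)}")
    arr = np.asarray(data, dtype=np.float64)
    if dtype == "float32":
        out = arr.astype("<f4")
    else:
        top = float(np.iinfo(_DTYPES[dtype]).max)
        out = np.clip(np.rint(arr / scale_max * top), 0, top).astype(
            np.dtype(_DTYPES[dtype]).newbyteorder("<"))
    pages = out if out.ndim >= 3 else out[None]
    tifffile.imwrite(path, pages, byteorder="<", photometric="minisblack")
    meta = dict(metadata or {})
    meta.setdefault("dtype", dtype)
    meta.setdefault("shape", list(np.asarray(data).shape))
    if dtype != "float32":
        meta.setdefault("scale_max", scale_max)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_tiff_stack(path) -> tuple[np.ndarray, dict]:
    """Read a multipage TIFF and its sidecar; round-trips float32 bit-exactly."""
    path = pathlib.Path(path)
    try:
        arr = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    shape = meta.get("shape")
    if shape and list(arr.shape) != list(shape):
        arr = arr.reshape(shape)
    return arr, meta


def _band_dict(band: SpectralBand | None):
    return None if band is None else asdict(band)


def _band_from(meta) -> SpectralBand | None:
    return None if not meta else SpectralBand(**meta)


def save_sinogram(s: Sinogram, path, dtype: str = "float32") -> pathlib.Path:
    meta = {
        "kind": "sinogram",
        "angles_deg": [float(a) for a in s.angles_deg],
        "spacing": s.spacing,
        "background_level": s.background_level,
        "channel": _band_dict(s.channel),
    }
    return write_tiff_stack(s.data, path, dtype=dtype, metadata=meta,
                            scale_max=max(s.background_level, float(s.data.max())))


def load_sinogram(path) -> Sinogram:
    arr, meta = read_tiff_stack(path)
    if meta.get("kind") != "sinogram":
        raise FormatError(f"{path} is not a sinogram stack (sidecar kind={meta.get('kind')!r})")
    data = np.asarray(arr, dtype=np.float64)
    if meta.get("dtype") in ("uint8", "uint16"):
        top = float(np.iinfo(np.dtype(meta["dtype"])).max)
        data = data / top * float(meta.get("scale_max", 1.0))
    return Sinogram(data, np.asarray(meta["angles_deg"]), float(meta["spacing"]),
                    float(meta["background_level"]), channel=_band_from(meta.get("channel")))


def save_volume(v: ChannelVolume, path, dtype: str = "float32") -> pathlib.Path:
    meta = {
        "kind": "volume",
        "voxel_size_um": v.voxel_size_um,
        "channel": _band_dict(v.channel),
        "provenance": v.provenance,
    }
    return write_tiff_stack(v.data, path, dtype=dtype, metadata=meta,
                            scale_max=max(1.0, float(v.data.max())))


def load_volume(path) -> ChannelVolume:
    arr, meta = read_tiff_stack(path)
    if meta.get("kind") != "volume":
        raise FormatError(f"{path} is not a volume stack (sidecar kind={meta.get('kind')!r})")
    return ChannelVolume(np.asarray(arr, dtype=np.float64),
                         voxel_size_um=float(meta.get("voxel_size_um", 1.0)),
                         channel=_band_from(meta.get("channel")),
                         provenance=meta.get("provenance", ""))


def write_landmarks(points: np.ndarray, path) -> pathlib.Path:
    """One ``x y z`` triple per line, voxel units; '#' starts a comment."""
    path = pathlib.Path(path)
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    lines = ["# x y z (voxel units)"]
    lines += [" ".join(f"{c:.9g}" for c in p) for p in pts]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_landmarks(path) -> np.ndarray:
    rows = []
    for line in pathlib.Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"landmark line needs 3 coordinates, got {line!r}")
        rows.append([float(p) for p in parts])
    if not rows:
        raise FormatError(f"no landmarks found in {path}")
    return np.asarray(rows)


def load_phantom_spec(path) -> list[EllipsePrimitive]:
    """Parse a YAML phantom specification into primitives.

    The file is a list of mappings with keys ``center``, ``axes``,
    ``rotation_deg``, ``intensity``, ``reflectance``, ``opaque``,
    ``transmittance`` (all but center/axes optional).
    """
    raw = yaml.safe_load(pathlib.Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise FormatError("phantom spec must be a non-empty list of primitives")
    prims = []
    for i, item in enumerate(raw):
        try:
            prims.append(EllipsePrimitive(
                center=tuple(item["center"]),
                semi_axes=tuple(item["axes"]),
                rotation_deg=float(item.get("rotation_deg", 0.0)),
                intensity=float(item.get("intensity", 0.0)),
                reflectance=tuple(item.get("reflectance", ())),
                opaque=bool(item.get("opaque", True)),
                transmittance=float(item.get("transmittance", 1.0)),
            ))
        except (KeyError, TypeError) as exc:
            raise FormatError(f"bad primitive #{i} in {path}: {exc}") from exc
    return prims


def save_phantom_spec(primitives: Sequence[EllipsePrimitive], path) -> pathlib.Path:
    path = pathlib.Path(path)
    items = [{
        "center": list(p.center),
        "axes": list(p.semi_axes),
        "rotation_deg": p.rotation_deg,
        "intensity": p.intensity,
        "reflectance": list(p.reflectance),
        "opaque": p.opaque,
        "transmittance": p.transmittance,
    } for p in primitives]
    path.write_text(yaml.safe_dump(items, sort_keys=False))
    return path


@dataclass
class RunConfig:
    """A reproducible description of one simulate/reconstruct run."""

    phantom_spec: str
    output_dir: str
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    recon: ReconSettings = field(default_factory=ReconSettings)
    grid_px: int = 128
    channels: int = 1
    mode: str = "reflective"
    seed: int = 0
    noise_sigma: float = 0.0


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    try:
        acq = AcquisitionConfig(**{k: v for k, v in raw.get("acquisition", {}).items()})
        rec = ReconSettings(**{k: v for k, v in raw.get("recon", {}).items()})
        cfg = RunConfig(
            phantom_spec=raw["phantom_spec"],
            output_dir=raw.get("output_dir", "."),
            acquisition=acq, recon=rec,
            grid_px=int(raw.get("grid_px", 128)),
            channels=int(raw.get("channels", 1)),
            mode=raw.get("mode", "reflective"),
            seed=int(raw.get("seed", 0)),
            noise_sigma=float(raw.get("noise_sigma", 0.0)),
        )
    except KeyError as exc:
        raise FormatError(f"run config {path} is missing key {exc}") from exc
    base = pathlib.Path(path).parent
    spec_path = base / cfg.phantom_spec
    if not spec_path.exists():
        raise FormatError(f"phantom spec {spec_path} does not exist")
    cfg.phantom_spec = str(spec_path)
    return cfg


def export_mesh_obj(mask, path, voxel_size_um: float | None = None) -> pathlib.Path:
    """Marching-cubes triangle mesh of a mask boundary, vertices in micrometers."""
    from skimage import measure as skmeasure

    m = np.asarray(mask.mask if hasattr(mask, "mask") else mask, dtype=np.float64)
    if m.ndim != 3:
        raise InvalidArgumentError("mesh export needs a 3D mask")
    if voxel_size_um is None:
        voxel_size_um = float(getattr(mask, "voxel_size_um", 1.0))
    verts, faces, _, _ = skmeasure.marching_cubes(m, level=0.5)
    verts = verts * voxel_size_um
    path = pathlib.Path(path)
    with path.open("w") as fh:
        fh.write("# triangle mesh, vertices in micrometers\n")
        for v in verts:
            fh.write(f"v {v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
        for f in faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")
    return path
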