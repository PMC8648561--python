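"""Shared voxel data model, volume I/O, cylindrical ROIs and seeded randomness.

Conventions used throughout the package:

* volumes are indexed ``(z, y, x)`` with ``z`` the rotation axis;
* indices are 0-based and the physical coordinate of the centre of voxel
  ``(i, j, k)`` is ``origin + voxel_size * (i, j, k)`` in micrometres;
* 16-bit volumes carry an affine ``scale = (offset, slope)`` such that
  ``physical = offset + slope * stored``.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np
import tifffile
import yaml

log = logging.getLogger("hiptomo")

__all__ = [
    "Volume3D",
    "CylinderROI",
    "RunConfig",
    "read_volume",
    "write_volume",
    "cylinder_mask",
    "rng_for",
]


@dataclass
class Volume3D:
    """A scalar voxel grid with isotropic physical sampling.

    Parameters
    ----------
    data:
        3D array ordered ``(z, y, x)``.
    voxel_size:
        Edge length of a voxel in micrometres (isotropic).
    origin:
        Physical coordinate (µm) of the centre of voxel ``(0, 0, 0)``.
    scale:
        ``(offset, slope)`` mapping stored integers to physical values; only
        meaningful for uint16 data, ``None`` for float volumes.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = tuple(float(v) for v in self.origin)  # type: ignore[assignment]
        if self.data.dtype == np.uint16:
            if self.scale is None:
                self.scale = (0.0, 1.0)
            if not self.scale[1] > 0:
                raise ValueError("uint16 scale slope must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def physical(self) -> np.ndarray:
        """Data in physical units (applies the uint16 scale if present)."""
        if self.data.dtype == np.uint16 and self.scale is not None:
            off, slope = self.scale
            return off + slope * self.data.astype(np.float32)
        return self.data

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (µm) of every voxel centre, as a sparse grid."""
        axes = [
            self.origin[d] + self.voxel_size * np.arange(self.shape[d], dtype=np.float64)
            for d in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore[return-value]


@dataclass
class CylinderROI:
    """A finite cylinder in physical coordinates (µm).

    The cylinder occupies axial positions ``t in [0, length]`` measured from
    ``axis_point`` along ``axis_direction`` and radial distances ``<= radius``.
    """

    axis_point: tuple[float, float, float]
    axis_direction: tuple[float, float, float]
    radius: float
    length: float

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.length > 0):
            raise ValueError("radius and length must be positive")
        d = np.asarray(self.axis_direction, dtype=np.float64)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")

    @property
    def volume(self) -> float:
        """Analytic cylinder volume pi * r^2 * L in µm^3."""
        return float(np.pi * self.radius**2 * self.length)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for an (N, 3) array of (z, y, x) µm points."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64)) - np.asarray(self.axis_point)
        d = np.asarray(self.axis_direction, dtype=np.float64)
        t = p @ d
        radial = np.linalg.norm(p - t[:, None] * d[None, :], axis=1)
        return (t >= 0.0) & (t <= self.length) & (radial <= self.radius)


def cylinder_mask(vol: Volume3D, roi: CylinderROI) -> Volume3D:
    """Binary mask of voxels whose centres lie inside the cylinder.

    Membership is evaluated at voxel centres and is inclusive at the
    boundary.  An empty intersection is allowed (a warning is logged).
    """
    zz, yy, xx = vol.coords()
    p0 = np.asarray(roi.axis_point, dtype=np.float64)
    d = np.asarray(roi.axis_direction, dtype=np.float64)
    dz, dy, dx = zz - p0[0], yy - p0[1], xx - p0[2]
    t = dz * d[0] + dy * d[1] + dx * d[2]
    r2 = (dz - t * d[0]) ** 2 + (dy - t * d[1]) ** 2 + (dx - t * d[2]) ** 2
    mask = (t >= 0.0) & (t <= roi.length) & (r2 <= roi.radius**2)
    if not mask.any():
        log.warning("cylinder ROI does not intersect the volume; empty mask")
    return Volume3D(mask, vol.voxel_size, vol.origin)


# ---------------------------------------------------------------------------
# volume I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_volume(vol: Volume3D, path: str | Path, format: str | None = None) -> None:
    """Write a volume as a multi-page TIFF stack or an HDF5 file.

    float32 round trips are lossless; uint16 volumes keep their grey-level
    scale in a JSON sidecar (TIFF) or in HDF5 attributes.  Writing uint16
    data containing NaN/Inf is refused.
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "tiff_stack")
    data = vol.data
    meta = {
        "voxel_size_um": vol.voxel_size,
        "origin_um": list(vol.origin),
        "scale": list(vol.scale) if vol.scale is not None else None,
    }
    if fmt == "tiff_stack":
        tifffile.imwrite(path, np.ascontiguousarray(data), photometric="minisblack")
        _sidecar_path(path).write_text(json.dumps(meta))
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            g = f.create_group("volume")
            g.create_dataset("data", data=data)
            g.attrs["voxel_size_um"] = vol.voxel_size
            g.attrs["origin_um"] = list(vol.origin)
            if vol.scale is not None:
                g.attrs["scale"] = list(vol.scale)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_volume(
    path: str | Path, format: str | None = None, voxel_size: float | None = None
) -> Volume3D:
    """Read a volume written by :func:`write_volume` (or a plain TIFF stack).

    For plain TIFF stacks without a sidecar the voxel size must be passed
    explicitly.  Slices of mixed shape raise a format error.
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "tiff_stack")
    if fmt == "tiff_stack":
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise ValueError(f"mixed slice shapes in stack: {sorted(shapes)}")
            data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        sidecar = _sidecar_path(path)
        origin = (0.0, 0.0, 0.0)
        scale = None
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            voxel_size = voxel_size or meta.get("voxel_size_um")
            origin = tuple(meta.get("origin_um", origin))
            if meta.get("scale") is not None:
                scale = tuple(meta["scale"])
        if voxel_size is None:
            raise ValueError("voxel size not in sidecar; pass voxel_size explicitly")
        return Volume3D(data, voxel_size, origin, scale)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            g = f["volume"]
            data = g["data"][()]
            vs = float(g.attrs["voxel_size_um"])
            origin = tuple(g.attrs.get("origin_um", (0.0, 0.0, 0.0)))
            scale = tuple(g.attrs["scale"]) if "scale" in g.attrs else None
        return Volume3D(data, voxel_size or vs, origin, scale)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# configuration and randomness


@dataclass
class RunConfig:
    """A scenario configuration: seed, scenario name and a parameter tree."""

    seed: int
    scenario: str
    params: dict[str, Any] = field(default_factory=dict)
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=int(doc.get("seed", 0)),
            scenario=str(doc.get("scenario", "default")),
            params=doc.get("params", {}) or {},
            outdir=str(doc.get("outdir", ".")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "scenario": self.scenario,
                    "params": self.params,
                    "outdir": self.outdir,
                },
                sort_keys=True,
            )
        )

    def rng(self, *keys: str) -> np.random.Generator:
        return rng_for(self.seed, *keys)


def rng_for(seed: int, *keys: str) -> np.random.Generator:
    """A reproducible, independent random stream keyed by (seed, *keys).

    Stream identities are derived with CRC32 of the key strings, so the same
    (seed, keys) pair yields the same stream on any platform.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
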