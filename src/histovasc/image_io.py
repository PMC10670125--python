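"""Reading and writing slice stacks, masks, landmark CSVs and voxel volumes.

Conventions used throughout the package: pixel centers sit at integer
coordinates, the origin is the top-left pixel, x points rightward and y
downward, indexing is 0-based.  Binary masks are stored on disk as
single-channel 8-bit images with values {0, 255}.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SliceImage",
    "LandmarkSet",
    "VoxelVolume",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "read_volume",
    "write_volume",
]

#: physical pixel size of the digitized slides, µm
DEFAULT_PIXEL_SIZE_UM = 0.5
#: microtome slice thickness, µm
DEFAULT_SLICE_THICKNESS_UM = 2.5

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class SliceImage:
    """One digitized histology slice: an RGB raster plus stack metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    index: int = 0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:  # grayscale input promoted to RGB
            self.pixels = np.stack([self.pixels] * 3, axis=-1)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB raster, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if self.pixels.shape[0] == 0 or self.pixels.shape[1] == 0:
            raise ValueError("empty image")
        if self.index < 0:
            raise ValueError("slice index must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]

    @property
    def diagonal_px(self) -> float:
        h, w = self.shape
        return float(np.hypot(h, w))


@dataclass
class LandmarkSet:
    """Ordered feature positions (x, y) in pixel units of one slice.

    Point *l* in one set corresponds to point *l* of the paired set; the
    order therefore carries the feature correspondence.
    """

    points: np.ndarray  # (N, 2) float, columns (x, y)
    frame: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"expected (N, 2) points, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class VoxelVolume:
    """3D binary occupancy grid indexed (z, y, x) with anisotropic spacing."""

    occupancy: np.ndarray  # (Z, Y, X) bool
    spacing_um: tuple[float, float, float] = (
        DEFAULT_SLICE_THICKNESS_UM,
        DEFAULT_PIXEL_SIZE_UM,
        DEFAULT_PIXEL_SIZE_UM,
    )

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"expected 3D occupancy grid, got {occ.ndim}D")
        if min(occ.shape) == 0:
            raise ValueError("volume dimensions must be > 0")
        if occ.dtype != bool:
            vals = np.unique(occ)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise ValueError("occupancy must be binary")
            occ = occ > 0
        self.occupancy = occ
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive reals (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def z_extent_um(self) -> float:
        """Physical axial extent: number of slices times the slice thickness."""
        return self.occupancy.shape[0] * self.spacing_um[0]


def _natural_key(name: str) -> list:
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def _list_image_files(path_pattern: str | Path) -> list[Path]:
    p = Path(path_pattern)
    if p.is_dir():
        files = [f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES]
    else:
        files = [Path(f) for f in p.parent.glob(p.name)]
        files = [f for f in files if f.suffix.lower() in _IMAGE_SUFFIXES]
    return sorted(files, key=lambda f: _natural_key(f.name))


def read_stack(
    path_pattern: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[SliceImage]:
    """Read an ordered slice stack from a directory or file glob.

    Files are ordered by natural sort of their names and assigned slice
    indices 0..N-1.  All images must share the same dimensions.
    """
    files = _list_image_files(path_pattern)
    if not files:
        raise FileNotFoundError(f"no slice images found at {path_pattern!s}")
    slices: list[SliceImage] = []
    shape: tuple[int, int] | None = None
    for i, f in enumerate(files):
        try:
            arr = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - re-raise with the file name
            raise OSError(f"cannot decode slice image {f}") from exc
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[:, :, :3]
        img = SliceImage(arr.astype(np.uint8, copy=False), index=i, pixel_size_um=pixel_size_um)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"slice {f} has shape {img.shape}, expected {shape} (mixed dimensions)"
            )
        slices.append(img)
    return slices


def write_stack(slices: Sequence[SliceImage], out_dir: str | Path, prefix: str = "slice") -> list[Path]:
    """Write a stack as numbered PNGs; inverse of :func:`read_stack`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    width = max(4, len(str(max(s.index for s in slices) if slices else 0)))
    for s in slices:
        p = out / f"{prefix}_{s.index:0{width}d}.png"
        iio.imwrite(p, s.pixels)
        paths.append(p)
    return paths


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask stored as an 8-bit image with values {0, 255}."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_landmarks(csv_path: str | Path, frame: str = "") -> LandmarkSet:
    """Read a landmark CSV (comma-separated, header with X and Y columns).

    Points are returned in file row order.  An optional leading index column
    is tolerated for compatibility with ANHIR-style files.
    """
    df = pd.read_csv(csv_path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{csv_path}: landmark CSV must have X and Y columns, got {list(df.columns)}")
    xy = df[[cols["x"], cols["y"]]]
    for col in xy.columns:
        bad = pd.to_numeric(xy[col], errors="coerce").isna() & xy[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{csv_path}: non-numeric value in column {col!r} at data row {row}")
    pts = xy.to_numpy(dtype=float)
    if np.isnan(pts).any():
        row = int(np.argwhere(np.isnan(pts))[0][0])
        raise ValueError(f"{csv_path}: missing coordinate at data row {row}")
    return LandmarkSet(pts, frame=frame or Path(csv_path).stem)


def write_landmarks(landmarks: LandmarkSet, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(landmarks.points, columns=["X", "Y"]).to_csv(csv_path, index=False)
    return csv_path


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a voxel volume as a multi-page TIFF (one page per z-slice).

    The anisotropic spacing is recorded in ImageJ-style metadata so that
    :func:`read_volume` inverts the write bit-exactly, spacing included.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sz, sy, sx = volume.spacing_um
    data = volume.occupancy.astype(np.uint8) * np.uint8(255)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a voxel volume written by :func:`write_volume`."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        meta = tf.imagej_metadata or {}
        sz = float(meta.get("spacing", DEFAULT_SLICE_THICKNESS_UM))
        page = tf.pages[0]
        def _res(tag_name: str) -> float:
            tag = page.tags.get(tag_name)
            if tag is None:
                return 1.0 / DEFAULT_PIXEL_SIZE_UM
            num, den = tag.value
            return num / den
        sx = 1.0 / _res("XResolution")
        sy = 1.0 / _res("YResolution")
    return VoxelVolume(data > 0, spacing_um=(sz, sy, sx))


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path
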