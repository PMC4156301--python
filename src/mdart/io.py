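"""File I/O for images and sinograms.

Two dialects: integer TIFF/PNG for phantoms and label maps, and raw
little-endian float payloads with a JSON sidecar (``<path>.json``) for
reconstructions and sinograms.  The raw dialect round-trips bit-exactly;
the sinogram sidecar carries the full projection geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import Image, ImageGrid, ProjectionGeometry, Sinogram

_INT_EXTS = {".png", ".tif", ".tiff"}
_RAW_EXT = ".raw"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: Image, path: str | Path) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _INT_EXTS:
        vals = image.values
        rounded = np.rint(vals)
        if not np.allclose(vals, rounded, atol=1e-9):
            raise ValueError(f"{ext} output requires integer-valued images")
        if rounded.min() < 0:
            raise ValueError("integer image formats require nonnegative values")
        dtype = np.uint8 if rounded.max() < 256 else np.uint16
        iio.imwrite(path, rounded.astype(dtype))
        _sidecar(path).write_text(json.dumps({"pixel_size": image.grid.pixel_size}))
    elif ext == _RAW_EXT:
        # little-endian raw payload; dtype recorded so float32 and float64
        # images both round-trip bit-exactly
        dtype = "<f4" if image.values.dtype == np.float32 else "<f8"
        payload = np.ascontiguousarray(image.values, dtype=dtype)
        path.write_bytes(payload.tobytes())
        meta = {
            "n_rows": image.grid.n_rows,
            "n_cols": image.grid.n_cols,
            "pixel_size": image.grid.pixel_size,
            "dtype": dtype,
        }
        _sidecar(path).write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported image extension {ext!r}")


def read_image(path: str | Path) -> Image:
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _INT_EXTS:
        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"expected a single-channel image, got shape {arr.shape}")
        pixel_size = 1.0
        if _sidecar(path).exists():
            pixel_size = float(json.loads(_sidecar(path).read_text())["pixel_size"])
        grid = ImageGrid(arr.shape[0], arr.shape[1], pixel_size)
        return Image(grid, arr)
    if ext == _RAW_EXT:
        meta = json.loads(_sidecar(path).read_text())
        grid = ImageGrid(int(meta["n_rows"]), int(meta["n_cols"]), float(meta["pixel_size"]))
        arr = np.frombuffer(path.read_bytes(), dtype=meta.get("dtype", "<f4"))
        if arr.size != grid.n_pixels:
            raise ValueError(
                f"payload holds {arr.size} values but sidecar declares {grid.n_pixels}"
            )
        return Image(grid, arr.reshape(grid.shape).astype(arr.dtype, copy=True))
    raise ValueError(f"unsupported image extension {ext!r}")


def write_sinogram(sinogram: Sinogram, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() != _RAW_EXT:
        raise ValueError("sinograms are stored as raw float payloads (.raw)")
    dtype = "<f4" if sinogram.values.dtype == np.float32 else "<f8"
    path.write_bytes(np.ascontiguousarray(sinogram.values, dtype=dtype).tobytes())
    meta = {"dtype": dtype, "geometry": sinogram.geometry.to_dict()}
    _sidecar(path).write_text(json.dumps(meta))


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    geometry = ProjectionGeometry.from_dict(meta["geometry"])
    arr = np.frombuffer(path.read_bytes(), dtype=meta.get("dtype", "<f4"))
    if arr.size != geometry.n_rays:
        raise ValueError(
            f"payload holds {arr.size} values but geometry declares {geometry.n_rays}"
        )
    return Sinogram(geometry, arr.reshape(geometry.n_angles, geometry.n_detectors).copy())
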