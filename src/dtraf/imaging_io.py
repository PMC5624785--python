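"""Image, mask and table I/O shared by every analysis stage.

Conventions
-----------
* Pixel (row, col) has its center at ``x = (col + 0.5) * pixel_size_um``,
  ``y = (row + 0.5) * pixel_size_um``; all distances are Euclidean in µm.
* Frame ``k`` occurs at ``k * frame_interval_s``; frame 0 is the release /
  bleach reference as tagged in the sidecar metadata.
* No operation accepts pixel data without calibration metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

__all__ = [
    "ImageStack",
    "RoiMask",
    "max_project",
    "rasterize_mask",
    "write_stack",
    "read_stack",
    "write_table",
    "read_table",
    "load_config",
    "save_config",
]


@dataclass
class ImageStack:
    """Calibrated multi-channel, multi-frame image data.

    ``data`` has shape ``(C, T, Y, X)`` for single-plane series or
    ``(C, T, Z, Y, X)`` for z-stacks. Counts are stored as float64 so that
    noise-free synthetic data round-trips measurement math exactly; they are
    quantized to uint16 only on disk.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"data must be (C,T,Y,X) or (C,T,Z,Y,X); got shape {self.data.shape}"
            )
        if self.pixel_size_um is None or not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be a positive number")
        if self.frame_interval_s is None or self.frame_interval_s < 0:
            raise ValueError("frame_interval_s must be >= 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 5

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, ..., Y, X) array for one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.data[idx]

    def plane(self, channel: str | int, frame: int = 0) -> np.ndarray:
        """Return one 2D plane (requires single-plane data)."""
        if self.has_z:
            raise ValueError("plane() requires projected (single-plane) data")
        idx = channel if isinstance(channel, int) else self.channel_names.index(channel)
        return self.data[idx, frame]


@dataclass
class RoiMask:
    """Label raster aligned to an :class:`ImageStack`.

    ``labels`` maps label value -> name (0 is always background).
    """

    raster: np.ndarray
    pixel_size_um: float
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ValueError("mask raster must be 2D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    def boolean(self, label: int) -> np.ndarray:
        return self.raster == label


def max_project(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection over z, per frame and channel.

    Single-plane input is returned unchanged (copy) with a warning.
    """
    if not stack.has_z:
        warnings.warn("max_project called on single-plane data; returning identity")
        return ImageStack(
            stack.data.copy(), stack.pixel_size_um, stack.frame_interval_s,
            list(stack.channel_names),
        )
    return ImageStack(
        stack.data.max(axis=2),
        stack.pixel_size_um,
        stack.frame_interval_s,
        list(stack.channel_names),
    )


def rasterize_mask(
    polygons: list[tuple[int, np.ndarray]],
    image_shape: tuple[int, int],
    pixel_size_um: float,
) -> RoiMask:
    """Rasterize labelled polygons (vertices in µm) onto a pixel grid.

    A pixel is assigned a label iff its center lies inside the polygon;
    later polygons overwrite earlier ones on overlap.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    n_rows, n_cols = image_shape
    raster = np.zeros((n_rows, n_cols), dtype=np.int32)
    if not polygons:
        return RoiMask(raster, pixel_size_um)
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    centers = np.column_stack(
        [(cols.ravel() + 0.5) * pixel_size_um, (rows.ravel() + 0.5) * pixel_size_um]
    )
    for label, verts in polygons:
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValueError("each polygon needs >= 3 (x, y) vertices")
        if not ShapelyPolygon(verts).is_valid:
            raise ValueError(f"polygon for label {label} is self-intersecting")
        inside = MplPath(verts).contains_points(centers)
        raster.ravel()[inside] = label
    return RoiMask(raster, pixel_size_um)


# ---------------------------------------------------------------------------
# TIFF + JSON-sidecar stack round trip
# ---------------------------------------------------------------------------

def write_stack(directory: str | Path, name: str, stack: ImageStack) -> Path:
    """Write one multi-page uint16 TIFF per channel plus a JSON sidecar.

    Returns the sidecar path. Pixel values are clipped to [0, 65535] and
    rounded; use in-memory stacks when exact float counts matter.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, ch in enumerate(stack.channel_names):
        pages = np.clip(np.round(stack.data[i]), 0, 65535).astype(np.uint16)
        # frame-major pages; z-stacks are flattened frame-then-z
        tifffile.imwrite(directory / f"{name}_{ch}.tif",
                         pages.reshape((-1,) + stack.frame_shape),
                         photometric="minisblack")
    sidecar = directory / f"{name}.json"
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channels": list(stack.channel_names),
        "n_frames": stack.n_frames,
        "n_z": stack.data.shape[2] if stack.has_z else 1,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_stack(sidecar_path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    Raises ``ValueError`` naming the field if calibration metadata is
    missing — a pixel size is never silently assumed.
    """
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_size_um", "frame_interval_s", "channels"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path.name} lacks required field {key!r}")
    name = sidecar_path.stem
    channels = []
    for ch in meta["channels"]:
        pages = tifffile.imread(sidecar_path.parent / f"{name}_{ch}.tif")
        if pages.ndim == 2:
            pages = pages[None]
        n_z = int(meta.get("n_z", 1))
        if n_z > 1:
            pages = pages.reshape(meta["n_frames"], n_z, *pages.shape[-2:])
        channels.append(pages.astype(np.float64))
    return ImageStack(
        np.stack(channels),
        float(meta["pixel_size_um"]),
        float(meta["frame_interval_s"]),
        list(meta["channels"]),
    )


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(path: str | Path, config: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config))
    else:
        path.write_text(json.dumps(config, indent=1))
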