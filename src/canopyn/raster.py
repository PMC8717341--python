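"""Lightweight raster containers and TIFF I/O.

A :class:`BandStack` holds named 2-D float layers over a common grid, with a
linear map from pixel indices to scene coordinates (origin at the upper-left
corner, row-major, north-up).  Stacks are written as multi-band TIFF files
with the georeferencing and layer names embedded as JSON in the
ImageDescription tag, so a stack round-trips through a single file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["BandStack", "CanopyHeightModel", "read_stack", "write_stack",
           "read_chm", "write_chm", "REFLECTANCE_BANDS"]

#: Reflectance band order used everywhere: blue/green/red/red-edge/NIR
#: (center wavelengths 475, 560, 668, 717 and 840 nm on the sensor emulated).
REFLECTANCE_BANDS = ("blue", "green", "red", "red_edge", "nir")


@dataclass
class BandStack:
    """Named 2-D layers sharing one grid.

    Parameters
    ----------
    layers : dict of str -> ndarray
        Each value is a 2-D float array; all must share the same shape.
    pixel_size_m : float
        Side length of a square pixel in metres.
    origin : (float, float)
        Scene (x, y) of the upper-left corner of pixel (0, 0).
    """

    layers: dict[str, np.ndarray]
    pixel_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers have mismatched shapes: {shapes}")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def band_names(self) -> list[str]:
        return list(self.layers)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"band {name!r} not in stack (have {self.band_names})") from None

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Scene (x, y) coordinates of every pixel center, as 2-D arrays."""
        ny, nx = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.pixel_size_m
        ys = y0 + (np.arange(ny) + 0.5) * self.pixel_size_m
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        return int((y - y0) // self.pixel_size_m), int((x - x0) // self.pixel_size_m)

    def crop(self, row0: int, col0: int, nrows: int, ncols: int) -> "BandStack":
        ny, nx = self.shape
        if row0 < 0 or col0 < 0 or row0 + nrows > ny or col0 + ncols > nx:
            raise ValueError("crop window exceeds raster extent")
        x0, y0 = self.origin
        return BandStack(
            {k: v[row0:row0 + nrows, col0:col0 + ncols].copy()
             for k, v in self.layers.items()},
            self.pixel_size_m,
            (x0 + col0 * self.pixel_size_m, y0 + row0 * self.pixel_size_m),
        )

    def to_array(self) -> np.ndarray:
        """(n_bands, ny, nx) array in band-name order."""
        return np.stack([self.layers[k] for k in self.layers])


@dataclass
class CanopyHeightModel:
    """Vegetation height above ground (metres), one value per cell."""

    heights: np.ndarray
    pixel_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    fill_method: str = "subcircle-max"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("CHM must be a 2-D raster")
        if np.nanmin(self.heights) < 0:
            raise ValueError("canopy heights must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def crop(self, row0: int, col0: int, nrows: int, ncols: int) -> "CanopyHeightModel":
        ny, nx = self.shape
        if row0 < 0 or col0 < 0 or row0 + nrows > ny or col0 + ncols > nx:
            raise ValueError("crop window exceeds raster extent")
        x0, y0 = self.origin
        return CanopyHeightModel(
            self.heights[row0:row0 + nrows, col0:col0 + ncols].copy(),
            self.pixel_size_m,
            (x0 + col0 * self.pixel_size_m, y0 + row0 * self.pixel_size_m),
            self.fill_method,
        )

    def resample_nearest(self, shape: tuple[int, int],
                         pixel_size_m: float) -> "CanopyHeightModel":
        """Nearest-neighbour resample onto a grid of the given shape/resolution."""
        ny, nx = shape
        rows = np.minimum(((np.arange(ny) + 0.5) * pixel_size_m
                           / self.pixel_size_m).astype(int), self.shape[0] - 1)
        cols = np.minimum(((np.arange(nx) + 0.5) * pixel_size_m
                           / self.pixel_size_m).astype(int), self.shape[1] - 1)
        return CanopyHeightModel(self.heights[np.ix_(rows, cols)], pixel_size_m,
                                 self.origin, self.fill_method)


def _meta_json(pixel_size_m: float, origin: tuple[float, float],
               band_names: list[str]) -> str:
    return json.dumps({"pixel_size_m": pixel_size_m, "origin": list(origin),
                       "band_names": band_names})


def write_stack(path, stack: BandStack) -> None:
    data = stack.to_array().astype(np.float32)
    tifffile.imwrite(path, data,
                     description=_meta_json(stack.pixel_size_m, stack.origin,
                                            stack.band_names))


def read_stack(path) -> BandStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    if data.ndim == 2:
        data = data[None]
    layers = {name: data[i].astype(float)
              for i, name in enumerate(meta["band_names"])}
    return BandStack(layers, meta["pixel_size_m"], tuple(meta["origin"]))


def write_chm(path, chm: CanopyHeightModel) -> None:
    tifffile.imwrite(path, chm.heights.astype(np.float32),
                     description=_meta_json(chm.pixel_size_m, chm.origin,
                                            ["height_m"]))


def read_chm(path) -> CanopyHeightModel:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return CanopyHeightModel(data.astype(float), meta["pixel_size_m"],
                             tuple(meta["origin"]))
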