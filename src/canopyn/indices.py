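"""Vegetation indices from 5-band multispectral reflectance.

The sensor provides blue, green, red, red-edge and NIR reflectance.  Fourteen
indices are derived per pixel and stacked with the five bands to give the
19-variable feature stack used by the nitrogen and habitat models.  Five of
the indices (GDVI, NDI blue/NIR, NDI red-edge/NIR, RI, VARI) are the ones the
downstream nitrogen model typically retains; the other nine come from the
standard multispectral plant-chemistry index literature and are held in a
registry so the set can be extended or replaced.

Division-by-zero pixels are emitted as NaN ("missing"), mirroring
masked-raster semantics: they are excluded from any later averaging.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .raster import REFLECTANCE_BANDS, BandStack

__all__ = ["INDEX_REGISTRY", "FEATURE_NAMES", "compute_index",
           "compute_feature_stack", "ndvi", "ndvi_mask"]


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with NaN where the denominator is zero."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    with np.errstate(invalid="ignore"):
        np.divide(num, den, out=out, where=ok)
    return out


def _nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Normalized difference (a - b) / (a + b)."""
    return _safe_div(a - b, a + b)


def _gdvi(b):       # Generalized Difference Vegetation Index
    return b["nir"] - b["green"]

def _ndi_b_nir(b):  # Normalized Difference Index blue/NIR
    return _nd(b["blue"], b["nir"])

def _ndi_re_nir(b):  # Normalized Difference Index red-edge/NIR
    return _nd(b["red_edge"], b["nir"])

def _ri(b):         # Redness Index
    return _nd(b["red"], b["green"])

def _vari(b):       # Visible Atmospherically Resistant Index
    return _safe_div(b["green"] - b["red"], b["green"] + b["red"] - b["blue"])

def _ndvi(b):
    return _nd(b["nir"], b["red"])

def _gndvi(b):
    return _nd(b["nir"], b["green"])

def _ndre(b):
    return _nd(b["nir"], b["red_edge"])

def _sr(b):         # simple ratio
    return _safe_div(b["nir"], b["red"])

def _grvi(b):       # green ratio vegetation index
    return _safe_div(b["nir"], b["green"])

def _evi(b):        # enhanced vegetation index (3-band)
    return _safe_div(2.5 * (b["nir"] - b["red"]),
                     b["nir"] + 6.0 * b["red"] - 7.5 * b["blue"] + 1.0)

def _ci_green(b):   # chlorophyll index, green
    return _safe_div(b["nir"], b["green"]) - 1.0

def _ci_rededge(b):  # chlorophyll index, red-edge
    return _safe_div(b["nir"], b["red_edge"]) - 1.0

def _savi(b, L=0.5):  # soil-adjusted vegetation index
    return _safe_div((1.0 + L) * (b["nir"] - b["red"]), b["nir"] + b["red"] + L)


#: name -> per-pixel formula over the five reflectance bands
INDEX_REGISTRY: dict[str, Callable] = {
    "gdvi": _gdvi,
    "ndi_b_nir": _ndi_b_nir,
    "ndi_re_nir": _ndi_re_nir,
    "ri": _ri,
    "vari": _vari,
    "ndvi": _ndvi,
    "gndvi": _gndvi,
    "ndre": _ndre,
    "sr": _sr,
    "grvi": _grvi,
    "evi": _evi,
    "ci_green": _ci_green,
    "ci_rededge": _ci_rededge,
    "savi": _savi,
}

#: stable order of the 19 feature layers: 5 bands then 14 indices
FEATURE_NAMES: tuple[str, ...] = REFLECTANCE_BANDS + tuple(INDEX_REGISTRY)


def compute_index(stack: BandStack, name: str) -> np.ndarray:
    """Compute one index layer from a reflectance stack.

    Raises ``KeyError`` for an unknown index name and for a missing band.
    """
    if name not in INDEX_REGISTRY:
        raise KeyError(f"unknown index {name!r}; known: {sorted(INDEX_REGISTRY)}")
    bands = {}
    fn = INDEX_REGISTRY[name]
    for band in REFLECTANCE_BANDS:
        if band in stack:
            bands[band] = stack[band]
    try:
        return fn(bands)
    except KeyError as exc:
        raise KeyError(f"index {name!r} needs reflectance band {exc}") from None


def compute_feature_stack(stack: BandStack) -> BandStack:
    """The 19-layer feature stack: 5 reflectance bands + 14 indices."""
    missing = [b for b in REFLECTANCE_BANDS if b not in stack]
    if missing:
        raise KeyError(f"reflectance bands missing from stack: {missing}")
    layers = {b: stack[b].copy() for b in REFLECTANCE_BANDS}
    for name in INDEX_REGISTRY:
        layers[name] = compute_index(stack, name)
    return BandStack(layers, stack.pixel_size_m, stack.origin)


def ndvi(stack: BandStack) -> np.ndarray:
    """(NIR - Red) / (NIR + Red), NaN where the denominator is zero."""
    return _nd(stack["nir"], stack["red"])


def ndvi_mask(stack: BandStack, ndvi_min: float) -> np.ndarray:
    """Boolean foliage mask: True where NDVI >= ndvi_min.

    Zero-denominator (undefined NDVI) pixels are always masked out.
    """
    values = ndvi(stack)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(values), False, values >= ndvi_min)
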