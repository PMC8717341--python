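"""Per-crown pixel extraction, subsampling and spectral summaries.

Each delineated crown is reduced to the foliage pixels inside its outline
that pass the NDVI mask; up to 1000 of them are subsampled at random per
tree, and the tree is summarized as the arithmetic mean of each of the 19
feature layers over those pixels (the mean of per-pixel index values, not
the index of mean reflectances).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from shapely import contains_xy

from .canopy import CrownSegment
from .raster import BandStack

__all__ = ["extract_crown_pixels", "subsample_pixels", "summarize_tree",
           "build_tree_summaries"]


def extract_crown_pixels(features: BandStack, crown: CrownSegment,
                         ndvi_min: float = 0.6,
                         tree_id: int | None = None) -> pd.DataFrame:
    """All pixels inside the crown outline that pass the NDVI foliage mask.

    Returns a table with columns ``tree_id, row, col`` plus one column per
    feature layer.  Pixels with any missing (NaN) feature are dropped so
    every row is a complete 19-vector.  A fully masked crown yields an empty
    table with a warning, not an error.
    """
    ny, nx = features.shape
    px = features.pixel_size_m
    x0, y0 = features.origin
    # only test pixels inside the polygon's bounding box
    bx0, by0, bx1, by1 = crown.polygon.bounds
    c0 = max(0, int((bx0 - x0) // px))
    c1 = min(nx, int((bx1 - x0) // px) + 1)
    r0 = max(0, int((by0 - y0) // px))
    r1 = min(ny, int((by1 - y0) // px) + 1)
    mask = np.zeros((ny, nx), dtype=bool)
    if r0 < r1 and c0 < c1:
        xs = x0 + (np.arange(c0, c1) + 0.5) * px
        ys = y0 + (np.arange(r0, r1) + 0.5) * px
        xx, yy = np.meshgrid(xs, ys)
        inside = contains_xy(crown.polygon, xx.ravel(), yy.ravel()
                             ).reshape(r1 - r0, c1 - c0)
        nir = features["nir"][r0:r1, c0:c1]
        red = features["red"][r0:r1, c0:c1]
        den = nir + red
        with np.errstate(invalid="ignore", divide="ignore"):
            ndvi_ok = np.where(den != 0, (nir - red) / np.where(den == 0, 1, den)
                               >= ndvi_min, False)
        mask[r0:r1, c0:c1] = inside & ndvi_ok
    rows, cols = np.nonzero(mask)
    tid = crown.tree_id if tree_id is None else tree_id
    data = {"tree_id": np.full(len(rows), tid, dtype=int),
            "row": rows, "col": cols}
    for name in features.band_names:
        data[name] = features[name][rows, cols]
    table = pd.DataFrame(data)
    feature_cols = [c for c in table.columns if c not in ("tree_id", "row", "col")]
    table = table.dropna(subset=feature_cols).reset_index(drop=True)
    if table.empty:
        warnings.warn(f"crown {tid}: no unmasked foliage pixels "
                      f"(ndvi_min={ndvi_min})", stacklevel=2)
    return table


def subsample_pixels(pixels: pd.DataFrame, n: int = 1000,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw min(n, available) rows without replacement, reproducibly."""
    if n <= 0:
        raise ValueError("subsample size must be positive")
    if len(pixels) <= n:
        return pixels.reset_index(drop=True)
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.choice(len(pixels), size=n, replace=False)
    return pixels.iloc[np.sort(idx)].reset_index(drop=True)


def summarize_tree(pixels: pd.DataFrame, lab: pd.Series | dict) -> dict:
    """Mean of each feature over the tree's pixels, plus its lab chemistry.

    ``lab`` supplies at least ``n_pct_dm`` (and optionally ``dign_pct_dm``)
    from the truth/laboratory table.  Missing feature values are excluded
    per feature.  Raises on an empty pixel table, naming the tree.
    """
    if pixels.empty:
        tid = lab.get("tree_id", "?") if hasattr(lab, "get") else "?"
        raise ValueError(f"tree {tid}: cannot summarize an empty pixel table")
    tid = int(pixels["tree_id"].iloc[0])
    feature_cols = [c for c in pixels.columns if c not in ("tree_id", "row", "col")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = {c: float(np.nanmean(pixels[c].to_numpy())) for c in feature_cols}
    out = {"tree_id": tid, "n_pixels": len(pixels), **means}
    out["n_pct_dm"] = float(lab["n_pct_dm"])
    out["dign_pct_dm"] = float(lab.get("dign_pct_dm", np.nan))
    if "plot_id" in lab:
        out["plot_id"] = int(lab["plot_id"])
    return out


def build_tree_summaries(features: BandStack, crowns: list[CrownSegment],
                         trees: pd.DataFrame, n_pixels: int = 1000,
                         default_ndvi_min: float = 0.6,
                         seed: int | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run extract -> subsample -> summarize for matched crowns.

    ``crowns`` must carry ``tree_id`` values present in ``trees``; per-tree
    NDVI thresholds come from a ``ndvi_min`` column when present, else the
    global default.  Returns (summaries, pooled subsampled pixel table).
    """
    rng = np.random.default_rng(seed)
    by_id = trees.set_index("tree_id")
    summaries, pixel_tables = [], []
    for crown in crowns:
        if crown.tree_id not in by_id.index:
            continue
        lab = by_id.loc[crown.tree_id]
        thr = float(lab["ndvi_min"]) if "ndvi_min" in lab.index else default_ndvi_min
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            px = extract_crown_pixels(features, crown, thr)
        if px.empty:
            continue
        px = subsample_pixels(px, n_pixels, rng=rng)
        pixel_tables.append(px)
        summaries.append(summarize_tree(px, lab))
    pixels = (pd.concat(pixel_tables, ignore_index=True)
              if pixel_tables else pd.DataFrame())
    return pd.DataFrame(summaries), pixels
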