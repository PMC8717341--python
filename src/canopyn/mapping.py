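"""Home-range-scale habitat maps and landscape summaries.

The fitted habitat classifier is applied across a 4-ha square around a plot
center, pixels below the field-measured minimum sub-canopy height are masked
to non-habitat using the CHM, the remaining canopy probability surface is
cut at the operating threshold into favorable / unfavorable classes, and the
map is summarized by mean/SD suitability, per-class areas and fractions, and
the FRAGSTATS-style clumpiness aggregation index.  Bitterlich point-sampling
expansion converts tallied stems to represented trees per hectare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import BandStack, CanopyHeightModel

__all__ = ["FAVORABLE", "UNFAVORABLE", "NON_HABITAT", "HabitatMap",
           "HabitatSummary", "crop_home_range", "predict_probability_raster",
           "mask_non_canopy", "classify_map", "summarize_habitat",
           "clumpiness", "bitterlich_expansion"]

FAVORABLE = 1        # canopy, P(N >= 1% DM) at or above threshold
UNFAVORABLE = 0      # canopy, below threshold
NON_HABITAT = 255    # understory, ground, or missing data


def crop_home_range(features: BandStack, chm: CanopyHeightModel,
                    center_xy: tuple[float, float], side_m: float = 200.0
                    ) -> tuple[BandStack, CanopyHeightModel]:
    """Aligned square crops (default 4 ha) of the feature stack and CHM.

    The CHM is first resampled (nearest neighbour) to the feature grid when
    the two resolutions differ.  Raises when the window leaves the raster.
    """
    px = features.pixel_size_m
    if chm.shape != features.shape or chm.pixel_size_m != px:
        chm = chm.resample_nearest(features.shape, px)
    n = int(round(side_m / px))
    cx, cy = center_xy
    row0 = int(round((cy - features.origin[1]) / px)) - n // 2
    col0 = int(round((cx - features.origin[0]) / px)) - n // 2
    return features.crop(row0, col0, n, n), chm.crop(row0, col0, n, n)


def predict_probability_raster(classifier, features: BandStack) -> np.ndarray:
    """Per-pixel probability of favorable habitat from a fitted classifier.

    Pixels with any missing feature value get NaN.  Raises ``KeyError``
    naming any feature layer the classifier needs but the stack lacks.
    """
    import pandas as pd

    cols = classifier.feature_names_
    missing = [c for c in cols if c not in features]
    if missing:
        raise KeyError(f"feature layers missing from stack: {missing}")
    ny, nx = features.shape
    flat = pd.DataFrame({c: features[c].ravel() for c in cols})
    ok = ~flat.isna().any(axis=1).to_numpy()
    proba = np.full(ny * nx, np.nan)
    if ok.any():
        proba[ok] = classifier.predict_score(flat[ok])
    return proba.reshape(ny, nx)


def mask_non_canopy(probability: np.ndarray, chm: CanopyHeightModel,
                    min_subcanopy_height_m: float) -> np.ndarray:
    """Set sub-canopy pixels (CHM below the field minimum) to missing."""
    if chm.shape != probability.shape:
        raise ValueError(
            f"probability raster {probability.shape} and CHM {chm.shape} "
            "are misaligned")
    out = np.asarray(probability, dtype=float).copy()
    out[chm.heights < min_subcanopy_height_m] = np.nan
    return out


@dataclass
class HabitatMap:
    """Masked probability surface plus its 3-class map."""

    probability: np.ndarray      # NaN exactly on non-habitat
    classes: np.ndarray          # FAVORABLE / UNFAVORABLE / NON_HABITAT
    pixel_size_m: float
    threshold: float


def classify_map(masked_probability: np.ndarray, threshold: float,
                 pixel_size_m: float) -> HabitatMap:
    """Cut the masked probability raster at the operating threshold.

    probability >= threshold -> favorable, < threshold -> unfavorable,
    missing -> non-habitat.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    p = np.asarray(masked_probability, dtype=float)
    classes = np.full(p.shape, NON_HABITAT, dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        classes[p >= threshold] = FAVORABLE
        classes[p < threshold] = UNFAVORABLE
    return HabitatMap(probability=p, classes=classes,
                      pixel_size_m=pixel_size_m, threshold=threshold)


@dataclass
class HabitatSummary:
    """Plot-level habitat description at the home-range scale."""

    mean_likelihood: float       # mean P(favorable) over canopy pixels
    sd_likelihood: float
    favorable_fraction_pct: float    # share of the whole 4-ha extent
    unfavorable_fraction_pct: float
    non_habitat_fraction_pct: float
    area_m2: dict[str, float]
    clumpiness: dict[str, float]
    n_canopy_pixels: int

    def to_dict(self) -> dict:
        return {
            "mean_likelihood": self.mean_likelihood,
            "sd_likelihood": self.sd_likelihood,
            "favorable_fraction_pct": self.favorable_fraction_pct,
            "unfavorable_fraction_pct": self.unfavorable_fraction_pct,
            "non_habitat_fraction_pct": self.non_habitat_fraction_pct,
            "area_m2": dict(self.area_m2),
            "clumpiness": dict(self.clumpiness),
            "n_canopy_pixels": self.n_canopy_pixels,
        }


def summarize_habitat(hmap: HabitatMap) -> HabitatSummary:
    """Mean/SD suitability, class areas and fractions, per-class clumpiness.

    Mean likelihood is computed over canopy pixels only (masking precedes
    the statistic); the favorable fraction uses the full extent - including
    non-habitat - as denominator, so the three class fractions sum to 100%.
    """
    c = hmap.classes
    total = c.size
    pixel_area = hmap.pixel_size_m ** 2
    counts = {"favorable": int((c == FAVORABLE).sum()),
              "unfavorable": int((c == UNFAVORABLE).sum()),
              "non_habitat": int((c == NON_HABITAT).sum())}
    canopy = counts["favorable"] + counts["unfavorable"]
    if canopy == 0:
        warnings.warn("map has no canopy pixels; likelihood undefined",
                      stacklevel=2)
        mean_l = sd_l = float("nan")
    else:
        vals = hmap.probability[c != NON_HABITAT]
        mean_l = float(np.mean(vals))
        sd_l = float(np.std(vals))
    clumpy = {name: clumpiness(c, code) for name, code in
              (("favorable", FAVORABLE), ("unfavorable", UNFAVORABLE),
               ("non_habitat", NON_HABITAT))}
    return HabitatSummary(
        mean_likelihood=mean_l, sd_likelihood=sd_l,
        favorable_fraction_pct=100.0 * counts["favorable"] / total,
        unfavorable_fraction_pct=100.0 * counts["unfavorable"] / total,
        non_habitat_fraction_pct=100.0 * counts["non_habitat"] / total,
        area_m2={k: v * pixel_area for k, v in counts.items()},
        clumpiness=clumpy, n_canopy_pixels=canopy)


def clumpiness(class_raster: np.ndarray, class_id: int) -> float:
    """FRAGSTATS CLUMPY aggregation index for one class, in [-1, 1].

    Uses rook (4-neighbour) adjacencies, double-counted, with no background
    exclusion.  With G the proportion of the class's adjacencies that are
    like-like and P its landscape proportion:

        CLUMPY = (G - P) / (1 - P)   if G >= P or P >= 0.5
                 (G - P) / P         otherwise

    A class covering the whole landscape returns 1 by convention; an absent
    class returns NaN.
    """
    c = np.asarray(class_raster)
    member = c == class_id
    n_class = int(member.sum())
    if n_class == 0:
        return float("nan")
    if n_class == c.size:
        return 1.0
    # adjacencies as ordered pairs with the first cell in the class: each
    # unordered rook pair contributes once per member cell (double count)
    like = 0
    involving = 0
    for axis in (0, 1):
        a = member.take(range(c.shape[axis] - 1), axis=axis)
        b = member.take(range(1, c.shape[axis]), axis=axis)
        like += 2 * int((a & b).sum())
        involving += int(a.sum()) + int(b.sum())
    if involving == 0:
        return float("nan")
    g = like / involving
    p = n_class / c.size
    if g >= p or p >= 0.5:
        return (g - p) / (1 - p)
    return (g - p) / p


def bitterlich_expansion(dbh_m, c: float = 25.0) -> np.ndarray | float:
    """Represented trees per hectare for a stem tallied by angle-count
    (Bitterlich) sampling: 10000 / (pi * c^2 * d^2), with gauge constant
    ``c`` (25 for a basal-area factor of 4) and diameter ``d`` in metres.
    """
    d = np.asarray(dbh_m, dtype=float)
    if np.any(d <= 0):
        raise ValueError("DBH must be positive")
    if c <= 0:
        raise ValueError("expansion factor must be positive")
    out = 10_000.0 / (np.pi * c ** 2 * d ** 2)
    return float(out) if np.isscalar(dbh_m) else out
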