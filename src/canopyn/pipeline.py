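"""End-to-end workflow helpers tying the pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canopy import (CrownSegment, detect_trees, fit_crown_width_model,
                     match_crowns_to_trees, segment_crowns)
from .indices import FEATURE_NAMES, compute_feature_stack
from .raster import BandStack, CanopyHeightModel
from .sampling import build_tree_summaries
from .synthetic import SceneConfig, SceneTruth, generate_scene

__all__ = ["SceneData", "delineate_crowns", "prepare_scene"]


@dataclass
class SceneData:
    """A rendered scene carried through delineation and pixel sampling."""

    config: SceneConfig
    stack: BandStack
    features: BandStack
    chm: CanopyHeightModel
    truth: SceneTruth
    markers: list[tuple[int, int]]
    crowns: list[CrownSegment]
    crown_labels: np.ndarray
    summaries: pd.DataFrame      # one row per matched tree, 19 feature means
    pixels: pd.DataFrame         # subsampled crown pixels, 19 features each

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in FEATURE_NAMES if c in self.summaries.columns]


def delineate_crowns(chm: CanopyHeightModel, field_trees: pd.DataFrame,
                     min_height_m: float = 10.0
                     ) -> tuple[list[tuple[int, int]], list[CrownSegment],
                                np.ndarray]:
    """Detect dominant trees and delineate crowns keyed to field tree ids.

    Fits the height -> crown-width allometry from the field table, runs the
    variable-window local-maximum detector and marker-controlled watershed,
    and re-keys the segments by the field tree whose stem they contain.
    Returns (markers, matched crowns, label raster).
    """
    window = fit_crown_width_model(field_trees)
    markers = detect_trees(chm, window, min_height_m)
    segments, labels = segment_crowns(chm, markers, min_height_m)
    matched = match_crowns_to_trees(segments, labels, field_trees,
                                    chm.pixel_size_m)
    return markers, matched, labels


def prepare_scene(config: SceneConfig, min_height_m: float = 10.0,
                  n_pixels: int = 1000, sampling_seed: int = 0) -> SceneData:
    """Generate a synthetic scene and run it through crown delineation,
    index computation and per-tree pixel sampling."""
    stack, chm, truth = generate_scene(config)
    features = compute_feature_stack(stack)
    markers, crowns, labels = delineate_crowns(chm, truth.trees, min_height_m)
    summaries, pixels = build_tree_summaries(
        features, crowns, truth.trees, n_pixels=n_pixels, seed=sampling_seed)
    return SceneData(config=config, stack=stack, features=features, chm=chm,
                     truth=truth, markers=markers, crowns=crowns,
                     crown_labels=labels, summaries=summaries, pixels=pixels)
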