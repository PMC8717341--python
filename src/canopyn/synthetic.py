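"""Synthetic multispectral forest scenes with known ground truth.

Emulates the inputs of a UAV canopy-nitrogen survey over tall eucalypt
forest: a 5-band reflectance orthomosaic (blue/green/red/red-edge/NIR), a
canopy height model, per-tree truth tables (position, species, DBH, height,
crown width, foliar N and digestible N in % dry matter), a plot network
spanning three elevation bands, and simulated nocturnal glider detections
driven by a plot-level logistic model.

The statistical structure downstream stages rely on is built in explicitly:

* foliar N is drawn per species around a species mean, species are sorted
  along the elevation gradient (lowest-N species in the lowlands);
* within each crown, green and NIR reflectance increase linearly with the
  tree's N (green reflectance relates to N absorption features directly,
  and the NIR-green difference GDVI is the strongest known multispectral N
  predictor), other bands carry little or no N signal;
* crowns are paraboloid domes, giving a single height maximum per tree so a
  local-maximum detector can recover the stem positions;
* crown width follows a linear allometry on height (plus noise), so the
  height->crown-width regression used by the tree detector is recoverable;
* ground/understory pixels get low NDVI and heights below the sub-canopy
  masking height.

Everything is reproducible: the config seed fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .raster import BandStack, CanopyHeightModel

__all__ = ["SceneConfig", "SceneTruth", "generate_tree_list", "render_scene",
           "simulate_detections", "generate_scene", "TREE_COLUMNS"]

TREE_COLUMNS = ["tree_id", "plot_id", "x", "y", "species", "dbh_m",
                "height_m", "crown_width_m", "n_pct_dm", "dign_pct_dm",
                "sampled", "ndvi_min"]

#: default species pool: name -> (mean foliar N % DM, SD).  Means bracket the
#: 0.63-1.92 % DM range observed across eucalypt canopy species.
DEFAULT_SPECIES_POOL: dict[str, tuple[float, float]] = {
    "sp_lowland_a": (0.85, 0.12),
    "sp_lowland_b": (1.00, 0.12),
    "sp_midhill_a": (1.20, 0.12),
    "sp_midhill_b": (1.35, 0.12),
    "sp_highland_a": (1.50, 0.12),
    "sp_highland_b": (1.65, 0.12),
}


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    ``extent_m`` is the side of the square scene (default 200 m = 4 ha, the
    glider home-range scale).  ``pixel_size_m`` defaults to 0.25 m so a 4-ha
    scene is 800x800 pixels; the survey's native 0.025 m remains valid but
    produces 100x the pixels.
    """

    extent_m: float = 200.0
    pixel_size_m: float = 0.25
    n_plots: int = 1
    elevation_bands: tuple[str, ...] = ("lowlands", "mid_hills", "high")
    trees_per_plot: int = 5           # sampled dominant trees (lab N known)
    background_trees_per_plot: int = 20
    species_pool: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_POOL))
    noise_sd: float = 0.01            # reflectance noise SD, per band per pixel
    within_crown_n_sd: float = 0.05   # SD of per-pixel N around the tree mean
    tree_band_sd: float = 0.02        # SD of per-tree per-band reflectance
    #   offsets (crown-level spectral individuality: canopy structure, LAI,
    #   shadow fraction); keeps band/index correlations below unity so the
    #   19 features are not a rank-1 function of N
    missing_dign_fraction: float = 0.2
    min_subcanopy_height_m: float = 5.0
    understory_height_max_m: float = 2.0
    ndvi_min: float = 0.6             # per-tree foliage-mask threshold default
    # reflectance link: band = b0 + b1 * N(pixel), N in % DM
    green_link: tuple[float, float] = (0.03, 0.05)
    nir_link: tuple[float, float] = (0.30, 0.15)
    red_edge_link: tuple[float, float] = (0.15, 0.02)
    blue_base: float = 0.04
    red_base: float = 0.04
    ground_reflectance: dict[str, float] = field(default_factory=lambda: {
        "blue": 0.06, "green": 0.12, "red": 0.15, "red_edge": 0.18,
        "nir": 0.20})
    # crown width = intercept + slope * height + N(0, sd), metres
    allometry: tuple[float, float, float] = (1.0, 0.22, 0.4)
    height_range_m: tuple[float, float] = (15.0, 35.0)
    detection_beta0: float = -5.6     # logit intercept of the detection model
    detection_beta1: float = 3.6      # logit slope on plot mean N (% DM)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m <= 0 or self.pixel_size_m <= 0:
            raise ValueError("extent_m and pixel_size_m must be positive")
        if self.n_plots < 1 or self.trees_per_plot < 1:
            raise ValueError("need at least one plot and one tree per plot")
        for sp, (mu, sd) in self.species_pool.items():
            if not (0.5 <= mu <= 2.0):
                raise ValueError(
                    f"species {sp!r} mean N {mu} outside the plausible "
                    "[0.5, 2.0] % DM bracket")
            if sd < 0:
                raise ValueError(f"species {sp!r} has negative N spread")

    # -- derived geometry -------------------------------------------------
    @property
    def plots_per_side(self) -> int:
        return math.ceil(math.sqrt(self.n_plots))

    @property
    def plot_cell_m(self) -> float:
        return self.extent_m / self.plots_per_side

    def max_crown_width_m(self) -> float:
        a, b, sd = self.allometry
        return a + b * self.height_range_m[1] + 3.0 * sd

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("elevation_bands", "green_link", "nir_link",
                    "red_edge_link", "allometry", "height_range_m"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "species_pool" in d:
            d["species_pool"] = {k: tuple(v) for k, v in d["species_pool"].items()}
        return cls(**d)


@dataclass
class SceneTruth:
    """Ground truth the pipeline must recover."""

    trees: pd.DataFrame
    plots: pd.DataFrame            # plot_id, x, y, elevation_band
    detections: pd.DataFrame       # plot_id, detected (0/1)
    min_subcanopy_height_m: float
    chm_truth: CanopyHeightModel
    label_truth: np.ndarray        # per-pixel class codes (see canopyn.mapping)
    tree_id_raster: np.ndarray     # -1 where no crown


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stage])


def _plot_centers(config: SceneConfig) -> pd.DataFrame:
    side = config.plots_per_side
    cell = config.plot_cell_m
    rows = []
    bands = config.elevation_bands
    per_band = math.ceil(config.n_plots / len(bands))
    for p in range(config.n_plots):
        r, c = divmod(p, side)
        rows.append({
            "plot_id": p,
            "x": (c + 0.5) * cell,
            "y": (r + 0.5) * cell,
            "elevation_band": bands[min(p // per_band, len(bands) - 1)],
        })
    return pd.DataFrame(rows)


def _band_species(config: SceneConfig) -> dict[str, list[str]]:
    """Partition the species pool across elevation bands, low N first."""
    ordered = sorted(config.species_pool, key=lambda s: config.species_pool[s][0])
    nb = len(config.elevation_bands)
    chunk = math.ceil(len(ordered) / nb)
    return {band: ordered[i * chunk:(i + 1) * chunk] or ordered
            for i, band in enumerate(config.elevation_bands)}


def generate_tree_list(config: SceneConfig) -> pd.DataFrame:
    """Place trees in every plot and draw their attributes.

    Trees are placed on a jittered grid (one tree per grid cell, jitter
    bounded so crowns stay inside their cell), which guarantees crowns never
    overlap and placement cost is linear in tree count.  Raises
    ``ValueError`` when the requested trees cannot fit at the maximum crown
    width the allometry can produce.
    """
    rng = _rng(config.seed, 1)
    plots = _plot_centers(config)
    band_species = _band_species(config)
    spacing = config.max_crown_width_m()
    cells_per_side = int(config.plot_cell_m // spacing)
    n_trees = config.trees_per_plot + config.background_trees_per_plot
    if cells_per_side ** 2 < n_trees:
        raise ValueError(
            f"overcrowded scene: {n_trees} trees per plot need more area than "
            f"a {config.plot_cell_m:.0f} m plot cell offers at crown spacing "
            f"{spacing:.1f} m ({cells_per_side ** 2} sites)")

    a, b, allo_sd = config.allometry
    h_lo, h_hi = config.height_range_m
    # per-species digestibility factor, constant within species
    dig_factor = {sp: rng.uniform(0.5, 1.0) for sp in config.species_pool}

    records = []
    tree_id = 0
    for _, plot in plots.iterrows():
        species_here = band_species[plot["elevation_band"]]
        cell_ids = rng.choice(cells_per_side ** 2, size=n_trees, replace=False)
        x0 = plot["x"] - config.plot_cell_m / 2
        y0 = plot["y"] - config.plot_cell_m / 2
        for j, cid in enumerate(cell_ids):
            cr, cc = divmod(int(cid), cells_per_side)
            height = rng.uniform(h_lo, h_hi)
            cw = max(1.0, a + b * height + rng.normal(0.0, allo_sd))
            cw = min(cw, spacing)        # crown must stay inside its cell
            slack = spacing - cw
            x = x0 + cc * spacing + cw / 2 + rng.uniform(0, slack)
            y = y0 + cr * spacing + cw / 2 + rng.uniform(0, slack)
            species = species_here[int(rng.integers(len(species_here)))]
            mu, sd = config.species_pool[species]
            n_pct = float(np.clip(rng.normal(mu, sd), 0.5, 2.0))
            dign = n_pct * dig_factor[species]
            if rng.uniform() < config.missing_dign_fraction:
                dign = np.nan
            records.append({
                "tree_id": tree_id,
                "plot_id": int(plot["plot_id"]),
                "x": x, "y": y,
                "species": species,
                "dbh_m": max(0.08, 0.025 * height + rng.normal(0.0, 0.05)),
                "height_m": height,
                "crown_width_m": cw,
                "n_pct_dm": n_pct,
                "dign_pct_dm": dign,
                "sampled": j < config.trees_per_plot,
                "ndvi_min": config.ndvi_min,
            })
            tree_id += 1
    return pd.DataFrame.from_records(records, columns=TREE_COLUMNS)


def reflectance_from_n(config: SceneConfig, n_pct_dm) -> dict[str, np.ndarray]:
    """The documented (invertible) canopy reflectance link, band -> value."""
    n = np.asarray(n_pct_dm, dtype=float)
    return {
        "blue": np.full_like(n, config.blue_base),
        "green": config.green_link[0] + config.green_link[1] * n,
        "red": np.full_like(n, config.red_base),
        "red_edge": config.red_edge_link[0] + config.red_edge_link[1] * n,
        "nir": config.nir_link[0] + config.nir_link[1] * n,
    }


def invert_green_reflectance(config: SceneConfig, green) -> np.ndarray:
    """Inverse of the green link: reflectance -> N % DM (noise-free case)."""
    g0, g1 = config.green_link
    return (np.asarray(green, dtype=float) - g0) / g1


def render_scene(trees: pd.DataFrame, config: SceneConfig
                 ) -> tuple[BandStack, CanopyHeightModel, SceneTruth]:
    """Rasterize trees into a 5-band reflectance stack, a CHM and truth.

    Crowns are paraboloid domes from the crown base (half the tree height)
    to the apex; cell value is the max over overlapping domes.  Canopy-pixel
    reflectance follows :func:`reflectance_from_n` evaluated at the pixel's
    N (tree N plus within-crown scatter), plus zero-mean Gaussian noise,
    clipped to [0, 1].
    """
    from .mapping import FAVORABLE, NON_HABITAT, UNFAVORABLE

    px = config.pixel_size_m
    n_cells = int(round(config.extent_m / px))
    rng = _rng(config.seed, 2)

    if len(trees) and (
            (trees["x"] - trees["crown_width_m"] / 2).min() < 0
            or (trees["y"] - trees["crown_width_m"] / 2).min() < 0
            or (trees["x"] + trees["crown_width_m"] / 2).max() > config.extent_m
            or (trees["y"] + trees["crown_width_m"] / 2).max() > config.extent_m):
        raise ValueError("tree crowns extend beyond the scene extent")

    chm = rng.uniform(0.0, config.understory_height_max_m, (n_cells, n_cells))
    tree_id_raster = np.full((n_cells, n_cells), -1, dtype=int)
    pixel_n = np.full((n_cells, n_cells), np.nan)

    centers = (np.arange(n_cells) + 0.5) * px
    for row in trees.itertuples():
        radius = row.crown_width_m / 2
        base = 0.5 * row.height_m          # crown base height
        c0 = max(0, int((row.x - radius) // px))
        c1 = min(n_cells, int((row.x + radius) // px) + 1)
        r0 = max(0, int((row.y - radius) // px))
        r1 = min(n_cells, int((row.y + radius) // px) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = centers[c0:c1] - row.x
        ys = centers[r0:r1] - row.y
        rr = np.sqrt(xs[None, :] ** 2 + ys[:, None] ** 2) / radius
        dome = row.height_m - (row.height_m - base) * rr ** 2
        inside = rr <= 1.0
        patch = chm[r0:r1, c0:c1]
        take = inside & (dome > patch)
        patch[take] = dome[take]
        tree_id_raster[r0:r1, c0:c1][take] = row.tree_id
        n_here = row.n_pct_dm + rng.normal(
            0.0, config.within_crown_n_sd, dome.shape)
        pixel_n[r0:r1, c0:c1][take] = n_here[take]

    canopy = tree_id_raster >= 0
    layers = {}
    link = reflectance_from_n(config, np.where(canopy, pixel_n, 0.0))
    # crown-level spectral individuality: one offset per tree per band
    max_id = int(trees["tree_id"].max()) + 1 if len(trees) else 0
    band_offsets = {band: rng.normal(0.0, config.tree_band_sd, max_id)
                    for band in config.ground_reflectance}
    for band, ground_val in config.ground_reflectance.items():
        vals = np.where(canopy, link[band], ground_val)
        if max_id and config.tree_band_sd > 0:
            vals = vals + np.where(canopy,
                                   band_offsets[band][tree_id_raster], 0.0)
        vals = vals + rng.normal(0.0, config.noise_sd, vals.shape)
        layers[band] = np.clip(vals, 0.0, 1.0)

    label = np.full((n_cells, n_cells), NON_HABITAT, dtype=np.uint8)
    if len(trees):
        n_by_id = trees.set_index("tree_id")["n_pct_dm"]
        tree_n = n_by_id.reindex(tree_id_raster[canopy]).to_numpy()
        label[canopy] = np.where(tree_n >= 1.0, FAVORABLE, UNFAVORABLE)

    plots = _plot_centers(config)
    sampled = trees[trees["sampled"]] if len(trees) else trees
    if len(sampled):
        plot_mean_n = sampled.groupby("plot_id")["n_pct_dm"].mean().reindex(
            plots["plot_id"]).to_numpy()
    else:
        plot_mean_n = np.full(len(plots), np.nan)
    detected = simulate_detections(
        np.nan_to_num(plot_mean_n), config.detection_beta0,
        config.detection_beta1, rng=_rng(config.seed, 3))
    detections = pd.DataFrame({"plot_id": plots["plot_id"],
                               "mean_n_pct_dm": plot_mean_n,
                               "detected": detected})

    chm_model = CanopyHeightModel(chm, px, fill_method="synthetic-dome")
    stack = BandStack(layers, px)
    truth = SceneTruth(trees=trees, plots=plots, detections=detections,
                       min_subcanopy_height_m=config.min_subcanopy_height_m,
                       chm_truth=chm_model, label_truth=label,
                       tree_id_raster=tree_id_raster)
    return stack, chm_model, truth


def simulate_detections(plot_mean_n, beta0: float = -5.6, beta1: float = 3.6,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Bernoulli glider detections: P(detect) = logistic(beta0 + beta1*meanN).

    Defaults are the coefficients of the plot-level detection model
    (intercept -5.6, slope 3.6 per % N DM).
    """
    mean_n = np.asarray(plot_mean_n, dtype=float)
    if not (np.isfinite(beta1) and (np.isfinite(beta0) or beta0 == -np.inf)):
        raise ValueError("detection model coefficients must be finite")
    if rng is None:
        rng = np.random.default_rng(seed)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * mean_n)))
    return (rng.uniform(size=mean_n.shape) < p).astype(int)


def generate_scene(config: SceneConfig
                   ) -> tuple[BandStack, CanopyHeightModel, SceneTruth]:
    """Convenience: generate the tree list and render it in one call."""
    trees = generate_tree_list(config)
    return render_scene(trees, config)
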