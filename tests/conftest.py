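import numpy as np
import pandas as pd
import pytest

import canopyn as cn
from canopyn.synthetic import TREE_COLUMNS


@pytest.fixture(scope="session")
def model_scene() -> cn.SceneData:
    """A 4-plot synthetic study (400 m scene, 200 trees, low noise) carried
    through crown delineation and pixel sampling; shared by the model-level
    and acceptance tests."""
    cfg = cn.SceneConfig(extent_m=400.0, n_plots=4, trees_per_plot=5,
                         background_trees_per_plot=45, noise_sd=0.01, seed=7)
    return cn.prepare_scene(cfg, min_height_m=10.0, sampling_seed=0)


@pytest.fixture(scope="session")
def field_plots() -> pd.DataFrame:
    return cn.load_field_plots()


def make_trees(rows: list[dict]) -> pd.DataFrame:
    """Tree table from minimal dicts; remaining columns get defaults."""
    defaults = {"plot_id": 0, "species": "sp", "dbh_m": 0.5, "height_m": 25.0,
                "crown_width_m": 6.0, "n_pct_dm": 1.2, "dign_pct_dm": np.nan,
                "sampled": True, "ndvi_min": 0.6}
    out = []
    for i, row in enumerate(rows):
        rec = {"tree_id": i, **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out, columns=TREE_COLUMNS)
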