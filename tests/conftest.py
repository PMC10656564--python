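import numpy as np
import pandas as pd
import pytest

from canopymort import canopy, structure, synthforest
from canopymort.raster import Raster
from canopymort.synthforest import SceneConfig


@pytest.fixture(scope="session")
def small_scene():
    """A 200x200 m scene shared across tests (moderate relief)."""
    cfg = SceneConfig(extent_m=(200.0, 200.0), dtm_relief=(900.0, 1500.0),
                      seed=42)
    dtm = synthforest.generate_dtm(cfg)
    trees = synthforest.generate_trees(cfg, dtm)
    rendered = synthforest.render_scene(trees, cfg)
    trees = trees.assign(segment_label=trees["tree_id"] + 1)
    truth = canopy.SegmentMap(
        labels=rendered.tree_labels,
        table=pd.DataFrame({
            "label": trees["tree_id"].to_numpy() + 1,
            "apex_row": 0, "apex_col": 0,
            "apex_x": trees["x"], "apex_y": trees["y"],
            "apex_height": trees["height"], "n_pixels": 0,
        }),
    )
    return {"config": cfg, "dtm": dtm, "trees": trees,
            "rendered": rendered, "truth_segments": truth}


@pytest.fixture(scope="session")
def small_scene_competition(small_scene):
    comp = structure.compute_all_indices(
        small_scene["rendered"].chm, small_scene["truth_segments"],
        small_scene["trees"], radii=(15.0,))
    return comp


def make_cone_chm(trees, extent=(40.0, 40.0), cell=1.0):
    """Tiny deterministic CHM from explicit cone crowns (test helper)."""
    cfg = SceneConfig(extent_m=extent, cell_size_m=cell,
                      dtm_relief=(1000.0, 1000.0), intensity_per_ha=0.0,
                      seed=0)
    df = pd.DataFrame(trees)
    if "crown_shape" not in df:
        df["crown_shape"] = "cone"
    if "dead" not in df:
        df["dead"] = False
    if "dead_fraction" not in df:
        df["dead_fraction"] = 0.0
    if "predead" not in df:
        df["predead"] = False
    rendered = synthforest.render_scene(df, cfg)
    return df, rendered
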