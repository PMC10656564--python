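"""Neighborhood competition indices CCTH, CC66 and CVTH.

CCTH is the percent of a 15-m circular neighborhood covered by canopy
taller than the subject tree (its own crown excluded from the numerator);
CC66 uses 66% of the subject's height; CVTH is the coefficient of
variation of neighbor heights. CCTH <= CC66 always (subset property).
"""

import pandas as pd

from canopymort import canopy, structure, synthforest
from canopymort.synthforest import SceneConfig

cfg = SceneConfig(extent_m=(200.0, 200.0), dtm_relief=(1000.0, 1400.0), seed=4)
dtm = synthforest.generate_dtm(cfg)
trees = synthforest.generate_trees(cfg, dtm)
scene = synthforest.render_scene(trees, cfg)
trees = trees.assign(segment_label=trees["tree_id"] + 1)
truth = canopy.SegmentMap(
    labels=scene.tree_labels,
    table=pd.DataFrame({"label": trees["tree_id"] + 1, "apex_row": 0,
                        "apex_col": 0, "apex_x": trees["x"],
                        "apex_y": trees["y"],
                        "apex_height": trees["height"], "n_pixels": 0}))

comp = structure.compute_all_indices(scene.chm, truth, trees,
                                     radii=(15.0, 30.0))
for radius, grp in comp.groupby("radius"):
    print(f"radius {radius:5.0f} m: CCTH mean {grp['ccth'].mean():5.1f}%  "
          f"CC66 mean {grp['cc66'].mean():5.1f}%  "
          f"CVTH mean {grp['cvth'].mean():5.1f}%")
assert (comp["ccth"] <= comp["cc66"] + 1e-9).all()
print("CCTH <= CC66 holds for every record; a locally tallest tree has "
      "CCTH = 0 (no taller canopy around it).")
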