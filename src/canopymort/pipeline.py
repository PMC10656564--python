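"""End-to-end orchestration of the synthetic mortality analysis.

``run_all`` drives the full chain — scene generation, crown segmentation,
terrain covariates, competition indices, ray-traced crown shadow, dead-tree
calling and the statistical fits — writing every artifact as plain text
(CSV / .asc rasters / GeoJSON) plus a provenance manifest.  One global seed
deterministically derives all stage seeds, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import canopy, driverstats, mortality, structure, sunshadow, terrain
from .raster import Raster, read_ascii_grid, write_ascii_grid
from .synthforest import (
    GENERA, SceneConfig, TREE_COLUMNS, assign_mortality, assign_stands,
    generate_dtm, generate_stands, generate_trees, render_scene,
)

log = logging.getLogger("canopymort")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full synthetic analysis run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    dead_threshold: float = mortality.DEFAULT_THRESHOLD
    sweep_thresholds: tuple = mortality.DEFAULT_SWEEP
    radii: tuple = (15.0,)
    shadow: sunshadow.ShadowConfig = field(
        default_factory=sunshadow.ShadowConfig)
    years: float = mortality.DEFAULT_YEARS
    height_bin_m: float = 2.0
    ccth_bin_pct: float = 2.0
    shadow_bin_pct: float = 2.0
    unit_grid_m: float = 100.0          # mediation / binning statistical unit
    n_boot: int = 499
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed drives every stage
        self.scene = dataclasses.replace(
            self.scene, seed=derive_seed(self.seed, "scene"))
        self.shadow = dataclasses.replace(
            self.shadow, seed=derive_seed(self.seed, "shadow"))


# ---------------------------------------------------------------------------
# table / vector I/O
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    pass


def write_trees_csv(trees: pd.DataFrame, path) -> None:
    """Tree table CSV in the documented column order."""
    cols = [c for c in TREE_COLUMNS if c in trees.columns]
    extra = [c for c in trees.columns if c not in cols]
    trees[cols + extra].to_csv(path, index=False, float_format="%.6f")


def read_trees_csv(path) -> pd.DataFrame:
    trees = pd.read_csv(path)
    missing = [c for c in ("tree_id", "x", "y", "height") if c not in trees]
    if missing:
        raise SchemaError(f"tree table missing columns: {missing}")
    if "genus" in trees.columns:
        bad = ~trees["genus"].isin(GENERA)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise SchemaError(
                f"malformed genus {trees['genus'].iloc[row]!r} at row {row}")
    return trees


def write_stands_geojson(stands, path) -> None:
    from shapely.geometry import mapping

    features = [
        {"type": "Feature", "properties": {"stand_id": i},
         "geometry": mapping(poly)}
        for i, poly in enumerate(stands)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features},
                  fh, sort_keys=True)


def read_stands_geojson(path):
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    return [shape(f["geometry"]) for f in gj["features"]]


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def unit_bin_rates(
    trees: pd.DataFrame,
    value_col: str,
    bin_width: float,
    unit_col: str = "unit_id",
    dead_col: str = "drought_dead",
    years: float = mortality.DEFAULT_YEARS,
) -> pd.DataFrame:
    """Per-(unit, bin) mortality rates with tree-count weights.

    This is the observation set the weighted regressions run on: within
    each statistical unit, trees are binned along ``value_col`` and each
    (unit, bin) cell contributes one rate with weight = its tree count.
    """
    v = trees[value_col].to_numpy(dtype=float)
    centers = (np.floor(v / bin_width) + 0.5) * bin_width
    df = pd.DataFrame({
        "unit_id": trees[unit_col].to_numpy(),
        "bin_center": centers,
        "dead": trees[dead_col].to_numpy(dtype=bool),
    })
    agg = (df.groupby(["unit_id", "bin_center"])
           .agg(n_trees=("dead", "size"), n_dead=("dead", "sum"))
           .reset_index())
    agg["rate"] = 100.0 * agg["n_dead"] / agg["n_trees"] / years
    return agg


def _stage_seed(config: RunConfig, name: str) -> int:
    return derive_seed(config.seed, name)


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, outdir) -> dict:
    """Execute the full synthetic analysis chain and write all artifacts.

    Returns a report dict with the per-stage outputs; every table and
    raster is also written under ``outdir`` together with a manifest
    (config hash + derived seeds, no timestamps, so reruns are
    byte-identical).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    # -- scene ----------------------------------------------------------
    log.info("stage 1/7: synthetic scene")
    dtm = generate_dtm(config.scene)
    trees = generate_trees(config.scene, dtm)
    if len(trees) == 0:
        raise ValueError("scene generated no trees; increase intensity")
    scene0 = render_scene(trees, config.scene)  # pre-mortality CHM + labels
    truth_segments = canopy.SegmentMap(
        labels=scene0.tree_labels,
        table=pd.DataFrame({
            "label": trees["tree_id"].to_numpy() + 1,
            "apex_row": 0, "apex_col": 0,
            "apex_x": trees["x"], "apex_y": trees["y"],
            "apex_height": trees["height"],
            "n_pixels": 0,
        }),
    )
    trees = trees.assign(segment_label=trees["tree_id"] + 1)

    # -- competition (needed by the mortality process) -------------------
    log.info("stage 2/7: competition indices")
    comp = structure.compute_all_indices(
        scene0.chm, truth_segments, trees, radii=config.radii)
    comp15 = comp[comp["radius"] == config.radii[0]]

    trees = assign_mortality(
        trees, comp15, dtm, config.scene.mortality,
        seed=_stage_seed(config, "mortality"))
    scene = render_scene(trees, config.scene)  # repaint classes w/ dead crowns

    # -- segmentation (evaluation harness) -------------------------------
    log.info("stage 3/7: crown segmentation")
    markers = canopy.detect_markers(scene.chm)
    segmap = canopy.filter_small_trees(
        canopy.watershed_segment(scene.chm, markers), scene.chm)
    seg_eval = canopy.match_to_truth(segmap, trees)

    # -- terrain ----------------------------------------------------------
    log.info("stage 4/7: terrain covariates")
    slope, aspect = terrain.slope_aspect(dtm)
    twi_r = terrain.twi(dtm)
    rad = terrain.clear_sky_radiation(
        dtm, slope, aspect, config.shadow.date, hours=(10, 11, 12, 13, 14),
        latitude_deg=config.shadow.latitude_deg)

    # -- crown shadow ----------------------------------------------------
    log.info("stage 5/7: crown shadow ray tracing")
    shadows = sunshadow.compute_shadow_ratios(trees, config.shadow)

    # -- dead-tree calling and rates --------------------------------------
    log.info("stage 6/7: dead-tree calling and mortality rates")
    frac = mortality.crown_dead_fraction(scene.class_raster, truth_segments)
    frac_by_tree = frac.reindex(trees["segment_label"]).to_numpy()
    called_dead = mortality.flag_dead(frac_by_tree, config.dead_threshold)
    drought_dead, in_cohort = mortality.exclude_predead(
        called_dead, trees["predead"].to_numpy())
    sweep = mortality.threshold_sweep(
        frac_by_tree[in_cohort], config.sweep_thresholds, config.years)
    scores = mortality.detection_scores(
        called_dead[in_cohort], trees["dead"].to_numpy()[in_cohort])

    stands = generate_stands(config.scene)
    stand_id = assign_stands(trees, stands)
    grid_id = mortality.grid_units(trees, config.unit_grid_m)
    cohort = trees[in_cohort].copy()
    cohort["drought_dead"] = drought_dead[in_cohort]
    cohort["stand_id"] = stand_id[in_cohort]
    cohort["unit_id"] = grid_id[in_cohort]
    cohort = cohort.merge(
        comp15[["tree_id", "ccth", "cc66", "cvth"]], on="tree_id", how="left")
    cohort = cohort.merge(
        shadows[["tree_id", "crown_shadow_ratio"]], on="tree_id", how="left")

    rates_stands = mortality.mortality_rate(
        cohort["drought_dead"], cohort["stand_id"], cohort["genus"],
        config.years)
    rates_grid = mortality.mortality_rate(
        cohort["drought_dead"], cohort["unit_id"], cohort["genus"],
        config.years)

    # -- statistics -------------------------------------------------------
    log.info("stage 7/7: driver statistics")
    height_obs = unit_bin_rates(cohort, "height", config.height_bin_m,
                                years=config.years)
    height_series = driverstats.bin_weighted(
        height_obs["bin_center"], height_obs["rate"], height_obs["n_trees"],
        config.height_bin_m)
    pw = driverstats.piecewise_fit(height_series)

    ccth_obs = unit_bin_rates(cohort, "ccth", config.ccth_bin_pct,
                              years=config.years)
    ccth_series = driverstats.bin_weighted(
        ccth_obs["bin_center"], ccth_obs["rate"], ccth_obs["n_trees"],
        config.ccth_bin_pct)
    ccth_wls = driverstats.wls_fit(ccth_series)
    ccth_beta = driverstats.beta_fit(
        np.clip(ccth_obs["rate"].to_numpy() / 100.0 * config.years, 0, 1),
        ccth_obs["bin_center"], ccth_obs["n_trees"])

    unit_stats = (cohort.groupby("unit_id")
                  .agg(ccth=("ccth", "mean"),
                       shadow=("crown_shadow_ratio", "mean"),
                       height=("height", "mean"),
                       n_trees=("drought_dead", "size"),
                       n_dead=("drought_dead", "sum"))
                  .reset_index())
    unit_stats["rate"] = (100.0 * unit_stats["n_dead"]
                          / unit_stats["n_trees"] / config.years)
    med = None
    if len(unit_stats) >= 30:
        med = driverstats.mediation(
            unit_stats["ccth"], unit_stats["shadow"], unit_stats["rate"],
            unit_stats["n_trees"], n_boot=config.n_boot,
            seed=_stage_seed(config, "mediation"))

    # -- outputs ----------------------------------------------------------
    write_trees_csv(cohort, outdir / "trees.csv")
    write_ascii_grid(dtm, outdir / "dtm.asc")
    write_ascii_grid(scene.chm, outdir / "chm.asc")
    write_ascii_grid(scene.class_raster, outdir / "classes.asc")
    write_ascii_grid(segmap.labels, outdir / "segments.asc")
    write_ascii_grid(twi_r, outdir / "twi.asc")
    write_ascii_grid(rad, outdir / "radiation.asc")
    write_stands_geojson(stands, outdir / "stands.geojson")
    comp.to_csv(outdir / "competition.csv", index=False, float_format="%.6f")
    shadows.to_csv(outdir / "shadow.csv", index=False, float_format="%.6f")
    sweep.to_csv(outdir / "threshold_sweep.csv", index=False,
                 float_format="%.6f")
    rates_stands.to_csv(outdir / "rates_stands.csv", index=False,
                        float_format="%.6f")
    rates_grid.to_csv(outdir / "rates_grid.csv", index=False,
                      float_format="%.6f")

    fits = {
        "piecewise_height": {
            "n_breakpoints": pw.n_breakpoints,
            "breakpoints": list(pw.breakpoints),
            "slopes": list(pw.slopes),
            "r_squared": pw.r_squared,
        },
        "ccth_wls": {"slope": ccth_wls.slope, "r_squared": ccth_wls.r_squared,
                     "p_value": ccth_wls.p_value},
        "ccth_beta": {"slope": float(ccth_beta.coef[1]),
                      "p_value": float(ccth_beta.pvalues[1])},
        "segmentation": {"recall": seg_eval["recall"],
                         "precision": seg_eval["precision"],
                         "f_score": seg_eval["f_score"]},
        "dead_call": scores,
    }
    if med is not None:
        fits["mediation"] = {
            "path_a": med.path_a, "path_b": med.path_b,
            "indirect": med.indirect, "direct": med.direct,
            "ci": [med.ci_low, med.ci_high],
        }
    with open(outdir / "fits.json", "w") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True)

    manifest = {
        "config_hash": hashlib.sha256(
            repr(config).encode()).hexdigest(),
        "global_seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s)
                        for s in ("scene", "shadow", "mortality", "mediation")},
        "n_trees": int(len(trees)),
        "n_cohort": int(len(cohort)),
        "outputs": sorted(p.name for p in outdir.iterdir()
                          if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    report.update({
        "trees": trees, "cohort": cohort, "dtm": dtm, "chm": scene.chm,
        "segments": segmap, "segmentation_eval": seg_eval,
        "competition": comp, "shadows": shadows, "sweep": sweep,
        "rates_stands": rates_stands, "rates_grid": rates_grid,
        "height_series": height_series, "piecewise": pw,
        "ccth_series": ccth_series, "ccth_wls": ccth_wls,
        "ccth_beta": ccth_beta, "mediation": med,
        "detection_scores": scores, "manifest": manifest,
    })
    return report
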