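"""Dead-tree calling, drought mortality rates and detection scoring.

A tree is called dead when more than a threshold fraction (default 35%,
strict) of its crown pixels carry the dead-tree land-cover class.  Trees
already dead before the drought are excluded from both numerator and
denominator.  Rates are expressed as percent of the cohort dying per year
over the drought span (default 4 years), per statistical unit (forest
stand or 500-m grid cell) and per genus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .canopy import SegmentMap
from .raster import Raster
from .synthforest import CLASS_CODES

DEFAULT_THRESHOLD = 0.35
DEFAULT_SWEEP = (0.30, 0.35, 0.40, 0.45, 0.50)
DEFAULT_YEARS = 4.0


def crown_dead_fraction(class_raster: Raster, segments: SegmentMap,
                        dead_code: int = CLASS_CODES["dead_tree"]) -> pd.Series:
    """Fraction of each segment's pixels classified dead, indexed by label.

    Empty segments (no pixels) get NaN.
    """
    labels = np.asarray(segments.labels.values).ravel()
    if labels.shape != np.asarray(class_raster.values).ravel().shape:
        raise ValueError("class raster and segment raster are not aligned")
    classes = np.asarray(class_raster.values).ravel()
    fg = labels > 0
    top = int(labels.max()) if fg.any() else 0
    if len(segments.table):
        # labels absent from the raster (fully overtopped crowns) still
        # need a slot: they get 0/0 -> NaN
        top = max(top, int(segments.table["label"].max()))
    nmax = top + 1
    total = np.bincount(labels[fg], minlength=nmax)
    dead = np.bincount(labels[fg & (classes == dead_code)], minlength=nmax)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, dead / np.maximum(total, 1), np.nan)
    out_labels = segments.table["label"].to_numpy()
    return pd.Series(frac[out_labels], index=out_labels, name="dead_fraction")


def flag_dead(fractions, threshold: float = DEFAULT_THRESHOLD):
    """Dead iff the crown dead fraction strictly exceeds the threshold."""
    f = np.asarray(fractions, dtype=float)
    if np.nanmin(f, initial=0.0) < 0 or np.nanmax(f, initial=0.0) > 1:
        raise ValueError("fractions must lie in [0, 1]")
    flags = f > threshold
    if isinstance(fractions, pd.Series):
        return pd.Series(flags, index=fractions.index, name="dead")
    return flags


def threshold_sweep(
    fractions,
    thresholds=DEFAULT_SWEEP,
    years: float = DEFAULT_YEARS,
) -> pd.DataFrame:
    """Dead counts and rates across call thresholds (non-increasing)."""
    f = np.asarray(fractions, dtype=float)
    n = len(f)
    rows = []
    for th in thresholds:
        n_dead = int(np.count_nonzero(f > th))
        rate = 100.0 * n_dead / n / years if n else np.nan
        rows.append({"threshold": th, "n_trees": n, "n_dead": n_dead,
                     "rate_pct_per_year": rate})
    return pd.DataFrame(rows)


def exclude_predead(dead_flags, predead_flags):
    """Apply the pre-drought exclusion rule.

    Returns (drought_dead, in_cohort): a pre-drought dead tree is neither a
    drought death nor part of the denominator.
    """
    dead = np.asarray(dead_flags, dtype=bool)
    pre = np.asarray(predead_flags, dtype=bool)
    if dead.shape != pre.shape:
        raise ValueError("flag arrays are not aligned")
    return dead & ~pre, ~pre


def mortality_rate(
    dead_flags,
    unit_assignment,
    genus=None,
    years: float = DEFAULT_YEARS,
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Mortality table per (unit, genus) and pooled.

    rate = 100 · n_dead / n_trees / years.  Units with no trees yield a row
    with n_trees = 0 and a NaN rate only if explicitly present in the
    assignment; genus "All" rows pool across genera within each unit, and a
    unit "All" block pools across units.
    """
    df = pd.DataFrame({
        "unit_id": np.asarray(unit_assignment),
        "dead": np.asarray(dead_flags, dtype=bool),
    })
    df["genus"] = "All" if genus is None else np.asarray(genus)
    groups = [df]
    if genus is not None and include_pooled:
        pooled = df.copy()
        pooled["genus"] = "All"
        groups.append(pooled)
    long = pd.concat(groups, ignore_index=True)
    blocks = [long]
    if include_pooled:
        allunits = long.copy()
        allunits["unit_id"] = "All"
        blocks.append(allunits)
    long = pd.concat(blocks, ignore_index=True)
    agg = (long.groupby(["unit_id", "genus"], sort=False)
           .agg(n_trees=("dead", "size"), n_dead=("dead", "sum"))
           .reset_index())
    agg["years"] = years
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["rate_pct_per_year"] = np.where(
            agg["n_trees"] > 0,
            100.0 * agg["n_dead"] / agg["n_trees"] / years,
            np.nan,
        )
    return agg


def rate_from_counts(n_dead: float, n_trees: float,
                     years: float = DEFAULT_YEARS) -> float:
    """Annualized mortality rate (%) from cohort counts."""
    if n_trees <= 0:
        return float("nan")
    return 100.0 * n_dead / n_trees / years


def grid_units(trees: pd.DataFrame, grid_size: float = 500.0,
               origin: tuple[float, float] = (0.0, 0.0)) -> pd.Series:
    """Axis-aligned square-grid unit id per tree, anchored at ``origin``."""
    gx = np.floor((trees["x"].to_numpy(dtype=float) - origin[0]) / grid_size)
    gy = np.floor((trees["y"].to_numpy(dtype=float) - origin[1]) / grid_size)
    return pd.Series([f"g_{int(i)}_{int(j)}" for i, j in zip(gx, gy)],
                     index=trees.index, name="unit_id")


# ---------------------------------------------------------------------------
# land-cover classification
# ---------------------------------------------------------------------------

def classify_cover_pixels(
    spectral_features: pd.DataFrame,
    training_labels: pd.Series | None = None,
    feature_cols=None,
    label_col: str = "class_code",
    seed: int = 0,
    n_estimators: int = 100,
) -> dict:
    """Random-forest land-cover classification with a stratified 50/50 split.

    Half of the labelled pixels train the model, the held-out half scores
    it; predictions cover all pixels.  Returns predictions, held-out
    accuracy, confusion matrix and per-class precision/recall/F.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import confusion_matrix
    from sklearn.model_selection import train_test_split

    feature_cols = feature_cols or [c for c in spectral_features.columns
                                    if c.startswith("feat")]
    X = spectral_features[feature_cols].to_numpy()
    y = (training_labels if training_labels is not None
         else spectral_features[label_col]).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes in training, got {classes}")
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=0.5, stratify=y, random_state=seed)
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1)
    clf.fit(X[idx_train], y[idx_train])
    y_pred_test = clf.predict(X[idx_test])
    accuracy = float(np.mean(y_pred_test == y[idx_test]))
    cm = confusion_matrix(y[idx_test], y_pred_test, labels=classes)
    per_class = []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        recall = tp / cm[i].sum() if cm[i].sum() else 0.0
        precision = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
        f = (2 * precision * recall / (precision + recall)
             if precision + recall else 0.0)
        per_class.append({"class_code": int(c), "recall": recall,
                          "precision": precision, "f_score": f})
    return {
        "predictions": clf.predict(X),
        "accuracy": accuracy,
        "confusion_matrix": cm,
        "classes": classes,
        "per_class": pd.DataFrame(per_class),
        "model": clf,
    }


def detection_scores(predicted_dead, true_dead) -> dict:
    """Recall, precision and F-score of dead-tree calls vs truth."""
    pred = np.asarray(predicted_dead, dtype=bool)
    true = np.asarray(true_dead, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("cohorts are not aligned")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall else 0.0)
    return {"recall": recall, "precision": precision, "f_score": f,
            "tp": tp, "fp": fp, "fn": fn}
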