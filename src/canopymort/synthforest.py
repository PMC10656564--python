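"""Synthetic mixed-conifer forest scenes with a known mortality process.

The generator emulates the statistical structure of a Sierra-Nevada-style
mixed-conifer landscape: clustered stem positions (Thomas process), four
genera (*Abies*, *Cedrus*, *Pinus*, *Quercus*) occupying elevation niches in
that descending order, per-genus height distributions with a hard 24 m cap
for *Quercus*, power-law crown allometry, a smooth terrain surface, and a
drought-mortality process with a piecewise (negative-positive-negative)
tree-height effect plus a negative neighborhood-competition (CCTH) effect.
Because the mortality parameters are known, the downstream statistics can be
tested for parameter recovery.

Trees are carried as a :class:`pandas.DataFrame` with the columns in
``TREE_COLUMNS``; helper dataclasses hold the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .raster import Raster

GENERA = ("Abies", "Cedrus", "Pinus", "Quercus")

TREE_COLUMNS = [
    "tree_id", "x", "y", "height", "crown_radius", "crown_base_height",
    "genus", "crown_shape", "dead", "dead_fraction", "predead",
]

#: land-cover class codes used in rendered class rasters
CLASS_CODES = {
    "dead_tree": 1, "green_tree": 2, "grass": 3,
    "bare_ground": 4, "artificial": 5, "water": 6,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

#: mean spectral signature per class (5 synthetic features emulating the
#: separable information content of high-resolution aerial imagery)
CLASS_SPECTRA = {
    1: (0.55, 0.40, 0.30, 0.25, 0.10),   # dead tree: red/brown, low NIR
    2: (0.10, 0.35, 0.12, 0.70, 0.60),   # green tree: high NIR
    3: (0.20, 0.45, 0.25, 0.55, 0.35),   # grass
    4: (0.45, 0.42, 0.40, 0.35, 0.05),   # bare ground
    5: (0.70, 0.70, 0.70, 0.30, 0.00),   # artificial
    6: (0.05, 0.10, 0.08, 0.04, 0.90),   # water
}


class ConfigurationError(ValueError):
    """Raised when a scene configuration is internally inconsistent."""


@dataclass
class GenusNiche:
    """Gaussian elevation niche: relative genus weight ∝ prior·N(mean, sd)."""
    mean_elev_m: float
    sd_elev_m: float
    prior: float = 1.0


@dataclass
class HeightModel:
    """Weibull height distribution truncated at ``max_height_m``."""
    shape: float
    scale_m: float
    max_height_m: float


@dataclass
class MortalityParams:
    """Ground-truth drought-mortality model on the logit scale.

    P(dead) = expit(beta0 + piecewise_height(h) + ccth_slope·CCTH
                    + elev_quad·(elev_km − elev_center_km)² + ε),
    ε ~ N(0, noise_sd).  The height effect is continuous piecewise linear
    with two knots and three per-segment slopes (sign pattern −, +, − by
    default, matching the drought-response shape the analysis targets).
    """

    beta0: float = -0.5
    height_knots: tuple[float, float] = (14.0, 39.0)
    height_slopes: tuple[float, float, float] = (-0.08, 0.05, -0.07)
    ccth_slope: float = -0.02          # logit per % CCTH
    elev_center_m: float = 1700.0
    elev_quad: float = 0.5             # logit per km^2
    noise_sd: float = 0.3
    # dead-fraction sampling: Beta laws for dead vs live crowns; their
    # overlap controls how the apparent rate responds to the call threshold
    beta_dead: tuple[float, float] = (5.0, 2.2)
    beta_live: tuple[float, float] = (1.2, 12.0)
    predead_prob: float = 0.02

    def __post_init__(self) -> None:
        k1, k2 = self.height_knots
        if not k1 < k2:
            raise ConfigurationError("height knots must be strictly increasing")
        if not np.all(np.isfinite(self.height_slopes)):
            raise ConfigurationError("height slopes must be finite")

    def height_effect(self, height) -> np.ndarray:
        """Continuous piecewise-linear logit contribution of tree height."""
        h = np.asarray(height, dtype=float)
        k1, k2 = self.height_knots
        s1, s2, s3 = self.height_slopes
        return (
            s1 * np.minimum(h, k1)
            + s2 * np.clip(h - k1, 0.0, k2 - k1)
            + s3 * np.maximum(h - k2, 0.0)
        )

    def logit_mortality(self, height, ccth, elev_m) -> np.ndarray:
        e_km = (np.asarray(elev_m, dtype=float) - self.elev_center_m) / 1000.0
        return (
            self.beta0
            + self.height_effect(height)
            + self.ccth_slope * np.asarray(ccth, dtype=float)
            + self.elev_quad * e_km**2
        )


@dataclass
class SceneConfig:
    """Full description of a synthetic scene; ``seed`` fixes every draw."""

    extent_m: tuple[float, float] = (500.0, 500.0)
    cell_size_m: float = 1.0
    dtm_relief: tuple[float, float] = (730.0, 2650.0)
    dtm_smoothness_m: float = 120.0
    point_process: str = "thomas"      # "thomas" | "poisson"
    intensity_per_ha: float = 120.0
    mean_cluster_size: float = 8.0
    cluster_sd_m: float = 8.0
    genus_niches: dict = field(default_factory=lambda: {
        "Abies": GenusNiche(2250.0, 280.0),
        "Cedrus": GenusNiche(1750.0, 280.0),
        "Pinus": GenusNiche(1300.0, 280.0),
        "Quercus": GenusNiche(950.0, 220.0),
    })
    height_model: dict = field(default_factory=lambda: {
        "Abies": HeightModel(1.9, 18.0, 60.0),
        "Cedrus": HeightModel(1.9, 16.0, 55.0),
        "Pinus": HeightModel(1.8, 17.0, 70.0),
        # tallest oak observed in the emulated landscape: 24 m
        "Quercus": HeightModel(2.2, 11.0, 24.0),
    })
    crown_a: float = 0.6               # crown_radius = a * height^b
    crown_b: float = 0.7
    crown_base_fraction: float = 0.4
    mortality: MortalityParams = field(default_factory=MortalityParams)
    classifier_noise_sd: float = 0.05
    chm_quantization_m: float = 0.01
    mean_stand_area_m2: float = 144_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ConfigurationError("extent must be positive")
        if self.cell_size_m <= 0:
            raise ConfigurationError("cell size must be positive")
        if self.intensity_per_ha < 0:
            raise ConfigurationError("intensity must be non-negative")
        if self.dtm_relief[1] < self.dtm_relief[0]:
            raise ConfigurationError("dtm_relief max below min")

    @property
    def area_ha(self) -> float:
        return self.extent_m[0] * self.extent_m[1] / 1e4

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent deterministic stream derived from the scene seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------

def generate_dtm(config: SceneConfig) -> Raster:
    """Smooth random elevation surface spanning ``config.dtm_relief``.

    Gaussian-filtered white noise rescaled to the configured relief; the
    filter length scale (``dtm_smoothness_m``) keeps slopes gentle at the
    1-m default resolution.  Deterministic given the scene seed.
    """
    w, h = config.extent_m
    cs = config.cell_size_m
    ncols = max(1, int(round(w / cs)))
    nrows = max(1, int(round(h / cs)))
    lo, hi = config.dtm_relief
    rng = config.rng(stream=1)
    noise = rng.standard_normal((nrows, ncols))
    sigma = config.dtm_smoothness_m / cs
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    rng_v = smooth.max() - smooth.min()
    if rng_v == 0 or hi == lo:
        values = np.full((nrows, ncols), 0.5 * (lo + hi))
    else:
        values = (smooth - smooth.min()) / rng_v * (hi - lo) + lo
    return Raster(values=values, origin=(0.0, h), cell_size=cs)


def _sample_dtm(dtm: Raster, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elevation at points, nearest-cell lookup clipped to the grid."""
    nrows, ncols = dtm.shape
    col = np.clip(((x - dtm.origin[0]) / dtm.cell_size).astype(int), 0, ncols - 1)
    row = np.clip(((dtm.origin[1] - y) / dtm.cell_size).astype(int), 0, nrows - 1)
    return dtm.values[row, col]


# ---------------------------------------------------------------------------
# stems
# ---------------------------------------------------------------------------

def _truncated_weibull(rng, model: HeightModel, n: int) -> np.ndarray:
    """Inverse-CDF sampling of Weibull(shape, scale) truncated at the cap."""
    cap_u = 1.0 - np.exp(-((model.max_height_m / model.scale_m) ** model.shape))
    u = rng.uniform(0.0, cap_u, size=n)
    return model.scale_m * (-np.log1p(-u)) ** (1.0 / model.shape)


def genus_weights(config: SceneConfig, elev_m) -> pd.DataFrame:
    """Normalized genus membership weights at given elevations.

    Softmax-style niche model: weight ∝ prior · exp(−(e−μ)²/2σ²), normalized
    so the weights sum to one at every elevation.
    """
    e = np.atleast_1d(np.asarray(elev_m, dtype=float))
    cols = {}
    for genus in GENERA:
        niche = config.genus_niches[genus]
        cols[genus] = niche.prior * np.exp(
            -0.5 * ((e - niche.mean_elev_m) / niche.sd_elev_m) ** 2
        )
    w = pd.DataFrame(cols)
    total = w.sum(axis=1)
    # degenerate elevations far outside every niche: fall back to priors
    bad = total <= 0
    if bad.any():
        priors = np.array([config.genus_niches[g].prior for g in GENERA], float)
        w.loc[bad, :] = priors / priors.sum()
        total = w.sum(axis=1)
    return w.div(total, axis=0)


def _stem_positions(config: SceneConfig, rng) -> np.ndarray:
    w, h = config.extent_m
    if config.intensity_per_ha == 0:
        return np.empty((0, 2))
    if config.point_process == "poisson":
        n = rng.poisson(config.intensity_per_ha * config.area_ha)
        return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    if config.point_process != "thomas":
        raise ConfigurationError(f"unknown point process {config.point_process!r}")
    # Thomas cluster process; parents simulated in a buffered window so the
    # realized intensity inside the extent is unbiased at the edges
    buf = 4.0 * config.cluster_sd_m
    area_buf_ha = (w + 2 * buf) * (h + 2 * buf) / 1e4
    parent_intensity = config.intensity_per_ha / config.mean_cluster_size
    n_parents = rng.poisson(parent_intensity * area_buf_ha)
    px = rng.uniform(-buf, w + buf, n_parents)
    py = rng.uniform(-buf, h + buf, n_parents)
    counts = rng.poisson(config.mean_cluster_size, n_parents)
    cx = np.repeat(px, counts) + rng.normal(0, config.cluster_sd_m, counts.sum())
    cy = np.repeat(py, counts) + rng.normal(0, config.cluster_sd_m, counts.sum())
    inside = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
    return np.column_stack([cx[inside], cy[inside]])


def generate_trees(config: SceneConfig, dtm: Raster) -> pd.DataFrame:
    """Sample a tree table: positions, genus, height and crown geometry.

    Stems come from the configured point process; genus follows the
    elevation-niche model; heights are truncated per-genus Weibull draws.
    Crown radius follows ``a·height^b`` and conifer crowns are cones with
    the crown base at ``crown_base_fraction·height`` (oak crowns are
    spheres).  Live/dead state is left to :func:`assign_mortality`.
    """
    xmin, ymin, xmax, ymax = dtm.extent
    if xmax - xmin < config.extent_m[0] - 1e-9 or ymax - ymin < config.extent_m[1] - 1e-9:
        raise ConfigurationError("dtm does not cover the configured extent")
    rng = config.rng(stream=2)
    pos = _stem_positions(config, rng)
    n = len(pos)
    if n == 0:
        return pd.DataFrame(columns=TREE_COLUMNS)
    elev = _sample_dtm(dtm, pos[:, 0], pos[:, 1])
    weights = genus_weights(config, elev).to_numpy()
    cum = np.cumsum(weights, axis=1)
    u = rng.uniform(size=n)
    genus_idx = (u[:, None] > cum).sum(axis=1)
    genus = np.array(GENERA)[genus_idx]

    height = np.empty(n)
    for gi, g in enumerate(GENERA):
        mask = genus_idx == gi
        height[mask] = _truncated_weibull(rng, config.height_model[g], mask.sum())
    height = np.maximum(height, 1.0)

    crown_radius = config.crown_a * height ** config.crown_b
    crown_base = config.crown_base_fraction * height
    shape = np.where(genus == "Quercus", "sphere", "cone")

    return pd.DataFrame({
        "tree_id": np.arange(n),
        "x": pos[:, 0], "y": pos[:, 1],
        "height": height,
        "crown_radius": crown_radius,
        "crown_base_height": crown_base,
        "genus": genus,
        "crown_shape": shape,
        "dead": False,
        "dead_fraction": 0.0,
        "predead": False,
    })


# ---------------------------------------------------------------------------
# mortality process
# ---------------------------------------------------------------------------

def assign_mortality(
    trees: pd.DataFrame,
    competition: pd.DataFrame,
    dtm: Raster,
    params: MortalityParams,
    seed: int,
) -> pd.DataFrame:
    """Draw live/dead states and crown dead-pixel fractions.

    ``competition`` must hold one CCTH value per tree (columns ``tree_id``,
    ``ccth``); a missing record is an error naming the tree.  Dead crowns
    draw their dead fraction from ``params.beta_dead`` and live crowns from
    ``params.beta_live``, so the apparent mortality rate responds to the
    downstream call threshold the way overlapping crown-condition classes
    would in imagery.
    """
    rng = np.random.default_rng(seed)
    comp = competition.drop_duplicates("tree_id").set_index("tree_id")["ccth"]
    missing = trees.index[~trees["tree_id"].isin(comp.index)]
    if len(missing) > 0:
        tid = trees.loc[missing[0], "tree_id"]
        raise KeyError(f"no competition record for tree_id {tid}")
    ccth = comp.reindex(trees["tree_id"]).to_numpy(dtype=float)
    elev = _sample_dtm(dtm, trees["x"].to_numpy(), trees["y"].to_numpy())
    logit = params.logit_mortality(trees["height"].to_numpy(), ccth, elev)
    if params.noise_sd > 0:
        logit = logit + rng.normal(0.0, params.noise_sd, len(trees))
    p = expit(logit)
    dead = rng.uniform(size=len(trees)) < p

    frac = np.empty(len(trees))
    a_d, b_d = params.beta_dead
    a_l, b_l = params.beta_live
    frac[dead] = rng.beta(a_d, b_d, dead.sum())
    frac[~dead] = rng.beta(a_l, b_l, (~dead).sum())

    out = trees.copy()
    out["dead"] = dead
    out["dead_fraction"] = frac
    out["predead"] = rng.uniform(size=len(trees)) < params.predead_prob
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedScene:
    """Raster products of a synthetic scene.

    ``tree_labels`` is the ground-truth crown ownership map (pixel value =
    tree_id + 1, 0 = no crown) — the surface a perfect segmentation would
    recover.
    """
    chm: Raster
    class_raster: Raster
    spectral_features: pd.DataFrame
    tree_labels: Raster


def _crown_surface(tree, X, Y):
    """Crown top elevation above ground at cell centres (NaN off-crown)."""
    d = np.hypot(X - tree.x, Y - tree.y)
    h, cb, r = tree.height, tree.crown_base_height, tree.crown_radius
    if tree.crown_shape == "cone":
        z = h - (h - cb) * d / r
    else:  # sphere
        rad = min(r, (h - cb) / 2.0)
        zc = (h + cb) / 2.0
        with np.errstate(invalid="ignore"):
            z = zc + np.sqrt(rad**2 - d**2)
        # sphere horizontal extent may be smaller than the allometric radius
        z = np.where(d <= rad, z, np.nan)
    return np.where(d <= r, z, np.nan)


def render_scene(trees: pd.DataFrame, config: SceneConfig) -> RenderedScene:
    """Rasterize crowns to a CHM, land-cover classes and spectral features.

    The CHM pixel value is the maximum over overlapping crown surfaces
    (cone/sphere profiles), 0 on open ground, quantized to
    ``chm_quantization_m``.  Crown pixels of dead trees are painted with the
    dead-tree class in proportion to each tree's ``dead_fraction``; ground
    pixels split into grass/bare/artificial/water patches.  Five noisy
    spectral features with class-separable means are attached per pixel.
    """
    w, h = config.extent_m
    cs = config.cell_size_m
    ncols, nrows = int(round(w / cs)), int(round(h / cs))
    chm = np.zeros((nrows, ncols))
    owner = np.zeros((nrows, ncols), dtype=np.int64)  # tree_id + 1

    for tree in trees.itertuples(index=False):
        r = tree.crown_radius
        c0 = max(0, int((tree.x - r) / cs))
        c1 = min(ncols, int(np.ceil((tree.x + r) / cs)) + 1)
        r0 = max(0, int((h - tree.y - r) / cs))
        r1 = min(nrows, int(np.ceil((h - tree.y + r) / cs)) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        X = (cols + 0.5) * cs
        Y = h - (rows + 0.5) * cs
        z = _crown_surface(tree, X, Y)
        z = np.where(np.isnan(z), -np.inf, z)
        win = chm[r0:r1, c0:c1]
        better = z > win
        win[better] = z[better]
        owner[r0:r1, c0:c1][better] = tree.tree_id + 1

    q = config.chm_quantization_m
    chm = np.round(chm / q) * q

    # land-cover classes
    classes = np.zeros((nrows, ncols), dtype=np.int16)
    rng = config.rng(stream=3)
    # ground pattern: smoothed noise quantiles -> grass/bare/artificial/water
    gnoise = ndimage.gaussian_filter(rng.standard_normal((nrows, ncols)), 6.0)
    ground = owner == 0
    if ground.any():
        qs = np.quantile(gnoise[ground], [0.05, 0.10, 0.45])
        g = gnoise
        classes[ground & (g < qs[0])] = CLASS_CODES["water"]
        classes[ground & (g >= qs[0]) & (g < qs[1])] = CLASS_CODES["artificial"]
        classes[ground & (g >= qs[1]) & (g < qs[2])] = CLASS_CODES["bare_ground"]
        classes[ground & (g >= qs[2])] = CLASS_CODES["grass"]
    # crown pixels: green, then dead_fraction of each crown painted dead
    classes[~ground] = CLASS_CODES["green_tree"]
    frac_by_id = trees.set_index("tree_id")["dead_fraction"]
    for tid, frac in frac_by_id.items():
        if frac <= 0:
            continue
        rows, cols = np.nonzero(owner == tid + 1)
        npix = len(rows)
        if npix == 0:
            continue
        k = int(round(frac * npix))
        if k == 0:
            continue
        pick = rng.choice(npix, size=min(k, npix), replace=False)
        classes[rows[pick], cols[pick]] = CLASS_CODES["dead_tree"]

    # spectral features
    means = np.array([CLASS_SPECTRA[c] for c in sorted(CLASS_SPECTRA)])
    flat = classes.ravel()
    feats = means[flat - 1].astype(float)
    if config.classifier_noise_sd > 0:
        feats = feats + rng.normal(0, config.classifier_noise_sd, feats.shape)
    rows, cols = np.unravel_index(np.arange(flat.size), classes.shape)
    spectral = pd.DataFrame(
        feats, columns=[f"feat{i + 1}" for i in range(5)]
    )
    spectral.insert(0, "col", cols)
    spectral.insert(0, "row", rows)
    spectral["class_code"] = flat

    origin = (0.0, h)
    return RenderedScene(
        chm=Raster(chm, origin, cs),
        class_raster=Raster(classes, origin, cs, nodata=-1),
        spectral_features=spectral,
        tree_labels=Raster(owner, origin, cs, nodata=-1),
    )


# ---------------------------------------------------------------------------
# stands
# ---------------------------------------------------------------------------

def generate_stands(config: SceneConfig):
    """Voronoi tessellation of seeded points into stand polygons.

    The number of seed points is chosen so the mean stand area matches
    ``mean_stand_area_m2``; polygons are clipped to the scene extent.
    Returns a list of shapely Polygons.
    """
    from shapely.geometry import MultiPoint, box
    from shapely.ops import voronoi_diagram

    w, h = config.extent_m
    n = max(1, int(round(w * h / config.mean_stand_area_m2)))
    rng = config.rng(stream=4)
    pts = MultiPoint(np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)]))
    frame = box(0, 0, w, h)
    if n == 1:
        return [frame]
    cells = voronoi_diagram(pts, envelope=frame)
    polys = [cell.intersection(frame) for cell in cells.geoms]
    return [p for p in polys if not p.is_empty]


def assign_stands(trees: pd.DataFrame, stands) -> pd.Series:
    """Stand index per tree by stem point-in-polygon (−1 if outside all)."""
    from shapely import STRtree, points

    pts = points(trees["x"].to_numpy(), trees["y"].to_numpy())
    tree_index = STRtree(list(stands))
    out = np.full(len(trees), -1, dtype=int)
    q, s = tree_index.query(pts, predicate="intersects")
    out[q] = s
    return pd.Series(out, index=trees.index, name="stand_id")
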