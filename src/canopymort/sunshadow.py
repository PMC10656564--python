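"""Ray-traced crown shadow ratios and a reduced two-leaf ET response.

A tree's crown shadow ratio is the daytime-average percentage of its crown
surface shaded by neighboring crowns within a 15-m radius, evaluated by
casting rays from sampled crown-surface points toward the sun at half-hour
solar time steps (23 steps, 07:00-18:00, on a reference mid-summer date).
Crowns are closed-form solids — a vertical-axis finite cone for conifers
and a sphere for broadleaves — so each ray test is a quadratic.

The reduced two-leaf model converts a shadow ratio into a relative
transpiration rate by splitting the canopy into sunlit and shaded leaf
fractions with different radiation-driven per-leaf rates.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .terrain import solar_position

_EPS = 1e-9


class SunBelowHorizonError(ValueError):
    pass


@dataclass
class CrownSolid:
    """Crown envelope: vertical cone (apex up) or sphere.

    The cone has its apex at (x, y, height) and base radius
    ``crown_radius`` at ``crown_base_height``; the sphere is centred midway
    between crown base and top with radius
    ``min(crown_radius, (height − crown_base_height)/2)`` so it fits the
    crown depth.
    """

    shape: str
    x: float
    y: float
    height: float
    crown_base_height: float
    crown_radius: float

    def __post_init__(self) -> None:
        if self.shape not in ("cone", "sphere"):
            raise ValueError(f"unknown crown shape {self.shape!r}")
        if not self.crown_base_height < self.height:
            raise ValueError("crown base must be below tree top")

    @classmethod
    def from_tree(cls, tree) -> "CrownSolid":
        return cls(
            shape=tree.crown_shape, x=float(tree.x), y=float(tree.y),
            height=float(tree.height),
            crown_base_height=float(tree.crown_base_height),
            crown_radius=float(tree.crown_radius),
        )

    @property
    def sphere_center(self) -> np.ndarray:
        zc = 0.5 * (self.height + self.crown_base_height)
        return np.array([self.x, self.y, zc])

    @property
    def sphere_radius(self) -> float:
        return min(self.crown_radius,
                   0.5 * (self.height - self.crown_base_height))

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` points uniform on the crown surface (cone: lateral face)."""
        if self.shape == "sphere":
            v = rng.standard_normal((n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            return self.sphere_center + self.sphere_radius * v
        # cone lateral surface: area density grows linearly from the apex
        f = np.sqrt(rng.uniform(size=n))        # fraction of slant from apex
        theta = rng.uniform(0, 2 * np.pi, n)
        z = self.height - f * (self.height - self.crown_base_height)
        rho = f * self.crown_radius
        return np.column_stack([
            self.x + rho * np.cos(theta),
            self.y + rho * np.sin(theta),
            z,
        ])


def ray_intersects_solid(origins, sun_direction, solid: CrownSolid) -> np.ndarray:
    """Whether upward rays from ``origins`` toward the sun enter the solid.

    ``origins`` is (n, 3) or (3,); ``sun_direction`` points *toward* the
    sun and must have a positive vertical component.  Returns a boolean
    array (or scalar for a single origin).  Grazing starts on the solid's
    own surface do not count (t > 1e-9).
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.asarray(sun_direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("zero-length sun direction")
    d = d / norm
    if d[2] <= 0:
        raise ValueError("sun direction must point upward")
    if solid.shape == "sphere":
        hit = _ray_sphere(o, d, solid.sphere_center, solid.sphere_radius)
    else:
        hit = _ray_cone(o, d, solid)
    return hit if np.asarray(origins).ndim > 1 else bool(hit[0])


def _ray_sphere(o, d, center, radius) -> np.ndarray:
    oc = o - center
    b = oc @ d
    c = np.einsum("ij,ij->i", oc, oc) - radius**2
    disc = b * b - c
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t2 = -b + sq  # larger root
    return ok & (t2 > _EPS)


def _ray_cone(o, d, solid: CrownSolid) -> np.ndarray:
    h, cb, r = solid.height, solid.crown_base_height, solid.crown_radius
    k = r / (h - cb)
    ex = o[:, 0] - solid.x
    ey = o[:, 1] - solid.y
    ez = h - o[:, 2]                       # height below apex
    dx, dy, dz = d
    A = dx * dx + dy * dy - k * k * dz * dz
    B = 2 * (ex * dx + ey * dy + k * k * ez * dz)
    C = ex * ex + ey * ey - k * k * ez * ez
    hit = np.zeros(len(o), dtype=bool)

    def _accept(t):
        z = o[:, 2] + t * dz
        return (t > _EPS) & (z >= cb - _EPS) & (z <= h + _EPS)

    lin = np.abs(A) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lin = -C / B
    hit |= lin & (np.abs(B) > 1e-12) & _accept(t_lin)
    disc = B * B - 4 * A * C
    quad = ~lin & (disc >= 0)
    sq = np.sqrt(np.where(disc >= 0, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-B - sq) / (2 * A)
        t2 = (-B + sq) / (2 * A)
    hit |= quad & _accept(t1)
    hit |= quad & _accept(t2)
    # base disk at z = cb
    if abs(dz) > 1e-12:
        tb = (cb - o[:, 2]) / dz
        xb = ex + tb * dx
        yb = ey + tb * dy
        hit |= (tb > _EPS) & (xb * xb + yb * yb <= r * r)
    return hit


@dataclass
class ShadowConfig:
    """Study conditions for the shadow simulation."""

    neighborhood_radius: float = 15.0
    date: _dt.date = _dt.date(2016, 8, 1)
    latitude_deg: float = 37.42
    longitude_deg: float = -119.6
    time_steps: tuple = tuple(7.0 + 0.5 * i for i in range(23))  # 07:00-18:00
    n_surface_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surface_samples < 50:
            raise ValueError("need at least 50 surface samples")
        if any(not 0 <= t < 24 for t in self.time_steps):
            raise ValueError("time steps must be within [0, 24)")


@dataclass
class ShadowResult:
    tree_id: object
    step_fractions: np.ndarray          # NaN where the sun was below horizon
    crown_shadow_ratio: float           # %, mean over sunlit steps


def sun_vector(elev: float, azim: float) -> np.ndarray:
    """Unit vector toward the sun; azimuth clockwise from north."""
    return np.array([
        np.sin(azim) * np.cos(elev),   # east
        np.cos(azim) * np.cos(elev),   # north
        np.sin(elev),
    ])


def shadow_fraction_at_time(
    tree,
    neighbors,
    sun_elev: float,
    sun_azim: float,
    n_samples: int = 200,
    seed: int = 0,
) -> float:
    """Fraction of sampled crown-surface points shaded by neighbor crowns."""
    if sun_elev <= 0:
        raise SunBelowHorizonError("sun below horizon")
    solid = CrownSolid.from_tree(tree)
    rng = np.random.default_rng(seed)
    pts = solid.sample_surface(n_samples, rng)
    d = sun_vector(sun_elev, sun_azim)
    blocked = np.zeros(n_samples, dtype=bool)
    for nb in _iter_trees(neighbors):
        if blocked.all():
            break
        blocked |= ray_intersects_solid(pts, d, CrownSolid.from_tree(nb))
    return float(blocked.mean())


def _iter_trees(trees):
    if isinstance(trees, pd.DataFrame):
        return list(trees.itertuples(index=False))
    return list(trees)


def crown_shadow_ratio(tree, all_trees: pd.DataFrame,
                       config: ShadowConfig) -> ShadowResult:
    """Daytime-averaged crown shadow ratio of one tree.

    Neighbors are stems within ``config.neighborhood_radius`` of the tree
    (excluding itself).  Steps with the sun below the horizon are excluded
    from the average; the crown-surface sample is drawn once per tree from
    the configured seed and reused across time steps.
    """
    dx = all_trees["x"].to_numpy(dtype=float) - tree.x
    dy = all_trees["y"].to_numpy(dtype=float) - tree.y
    within = np.hypot(dx, dy) <= config.neighborhood_radius
    within &= all_trees["tree_id"].to_numpy() != tree.tree_id
    neighbors = all_trees.loc[within]
    return _shadow_for_tree(tree, neighbors, config)


def _shadow_for_tree(tree, neighbors, config: ShadowConfig) -> ShadowResult:
    solid = CrownSolid.from_tree(tree)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int(tree.tree_id)]))
    pts = solid.sample_surface(config.n_surface_samples, rng)
    nb_solids = [CrownSolid.from_tree(nb) for nb in _iter_trees(neighbors)]
    fractions = np.full(len(config.time_steps), np.nan)
    for i, t in enumerate(config.time_steps):
        elev, azim = solar_position(
            config.latitude_deg, config.longitude_deg, config.date, t)
        if elev <= 0:
            continue
        d = sun_vector(elev, azim)
        blocked = np.zeros(len(pts), dtype=bool)
        for nb in nb_solids:
            if blocked.all():
                break
            blocked |= ray_intersects_solid(pts, d, nb)
        fractions[i] = blocked.mean()
    if np.isnan(fractions).all():
        raise SunBelowHorizonError("sun below horizon at every time step")
    ratio = 100.0 * float(np.nanmean(fractions))
    return ShadowResult(tree_id=tree.tree_id, step_fractions=fractions,
                        crown_shadow_ratio=ratio)


def compute_shadow_ratios(trees: pd.DataFrame,
                          config: ShadowConfig) -> pd.DataFrame:
    """Crown shadow ratio for every tree in the table."""
    xy = trees[["x", "y"]].to_numpy(dtype=float)
    kdt = cKDTree(xy)
    neighbor_lists = kdt.query_ball_point(xy, config.neighborhood_radius)
    rows = []
    tuples = list(trees.itertuples(index=False))
    for i, tree in enumerate(tuples):
        nb = [tuples[j] for j in neighbor_lists[i] if j != i]
        res = _shadow_for_tree(tree, nb, config)
        rows.append({"tree_id": tree.tree_id,
                     "crown_shadow_ratio": res.crown_shadow_ratio,
                     **{f"step_{k}": v
                        for k, v in enumerate(res.step_fractions)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reduced two-leaf ET response
# ---------------------------------------------------------------------------

@dataclass
class TwoLeafParams:
    """Sunlit/shaded leaf partition and light-response parameters.

    ``shadow_grid`` / ``sunlit_grid`` define the (piecewise-linear) mapping
    from crown shadow ratio (%) to the sunlit-to-total leaf area ratio,
    linearly extrapolated outside the tabulated range.  Per-leaf
    transpiration follows a saturating light response e(Q) = Q/(Q+Q_half)
    with relative irradiances Q_sun (direct+diffuse) and Q_shade (diffuse
    only), so sunlit leaves always transpire faster than shaded ones.
    """

    shadow_grid: tuple = (73.0, 76.0, 79.0, 82.0, 85.0, 88.0, 91.0)
    sunlit_grid: tuple = (0.17, 0.15, 0.13, 0.11, 0.09, 0.07, 0.05)
    q_sun: float = 1.0
    q_shade: float = 0.15
    q_half: float = 0.3

    def leaf_rate(self, q: float) -> float:
        return q / (q + self.q_half)

    def sunlit_fraction(self, shadow_ratio_pct: float) -> float:
        s = np.asarray(self.shadow_grid, dtype=float)
        f = np.asarray(self.sunlit_grid, dtype=float)
        slope = (f[-1] - f[0]) / (s[-1] - s[0])
        x = float(shadow_ratio_pct)
        if x < s[0]:
            return float(f[0] + slope * (x - s[0]))
        if x > s[-1]:
            return float(f[-1] + slope * (x - s[-1]))
        return float(np.interp(x, s, f))


def relative_et_two_leaf(
    shadow_ratio_pct: float,
    sunlit_to_total_leaf_ratio: float | None = None,
    params: TwoLeafParams | None = None,
) -> float:
    """Canopy transpiration relative to an unshaded reference tree.

    ET_rel = [f·e_sun + (1−f)·e_shade] / [f0·e_sun + (1−f0)·e_shade]
    where f is the sunlit leaf fraction at the given shadow ratio (taken
    from the configured mapping unless passed explicitly) and f0 the
    sunlit fraction of the zero-shadow reference.
    """
    params = params or TwoLeafParams()
    f = (params.sunlit_fraction(shadow_ratio_pct)
         if sunlit_to_total_leaf_ratio is None
         else float(sunlit_to_total_leaf_ratio))
    if not 0 < f <= 1:
        raise ValueError("sunlit leaf fraction must be in (0, 1]")
    f0 = params.sunlit_fraction(0.0)
    e_sun = params.leaf_rate(params.q_sun)
    e_shade = params.leaf_rate(params.q_shade)
    num = f * e_sun + (1 - f) * e_shade
    den = f0 * e_sun + (1 - f0) * e_shade
    return num / den
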