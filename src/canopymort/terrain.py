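"""Terrain derivatives used as environmental covariates.

Slope and aspect from the Horn 3x3 kernel, D8 flow accumulation, the
topographic wetness index TWI = ln(a / tan beta), and a simplified clear-sky
solar radiation surface (direct beam on the tilted surface plus an isotropic
diffuse term).  Solar geometry uses the standard declination / hour-angle
formulas in local solar time.
"""

from __future__ import annotations

import datetime as _dt
import warnings

import numpy as np

from .raster import Raster

SOLAR_CONSTANT = 1367.0  # W/m^2

#: D8 neighbor offsets (drow, dcol), clockwise from east
_D8 = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


class EmptyRasterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# slope / aspect
# ---------------------------------------------------------------------------

def slope_aspect(dtm: Raster) -> tuple[Raster, Raster]:
    """Slope and aspect (radians) from the Horn finite-difference kernel.

    Aspect is the downslope direction measured clockwise from north; flat
    cells get aspect = nodata.  Edge cells use replicated borders.
    """
    valid = dtm.valid_mask
    if not valid.any():
        raise EmptyRasterError("all-nodata raster")
    z = np.where(valid, dtm.values, np.nan).astype(float)
    # odd reflection preserves the gradient of an inclined plane at borders
    if min(z.shape) >= 2:
        zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    else:
        zp = np.pad(z, 1, mode="edge")
    cs = dtm.cell_size

    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)   # east
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)   # north

    slope = np.arctan(np.hypot(dzdx, dzdy))
    # downslope vector (east, north) = (-dzdx, -dzdy); clockwise from north
    aspect = np.mod(np.arctan2(-dzdx, -dzdy), 2 * np.pi)
    flat = np.hypot(dzdx, dzdy) == 0
    aspect = np.where(flat, dtm.nodata, aspect)
    slope = np.where(np.isnan(slope), dtm.nodata, slope)
    aspect = np.where(np.isnan(aspect), dtm.nodata, aspect)
    return dtm.copy_with(slope), dtm.copy_with(aspect)


# ---------------------------------------------------------------------------
# D8 flow accumulation
# ---------------------------------------------------------------------------

def _fill_single_cell_pits(z: np.ndarray) -> np.ndarray:
    """Raise cells that are strictly lower than all 8 neighbors."""
    zp = np.pad(z, 1, mode="edge")
    nmin = np.full_like(z, np.inf)
    for dr, dc in _D8:
        nmin = np.minimum(nmin, zp[1 + dr: zp.shape[0] - 1 + dr,
                                   1 + dc: zp.shape[1] - 1 + dc])
    out = z.copy()
    interior = np.zeros_like(z, dtype=bool)
    interior[1:-1, 1:-1] = True
    pit = interior & (z < nmin)
    out[pit] = nmin[pit]
    return out


def _d8_directions(z: np.ndarray, cell_size: float) -> np.ndarray:
    """Steepest-descent D8 direction index per cell, -1 = no lower neighbor."""
    nrows, ncols = z.shape
    best = np.full((nrows, ncols), -1, dtype=np.int8)
    best_grad = np.zeros((nrows, ncols))
    for k, (dr, dc) in enumerate(_D8):
        dist = cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        shifted = np.full_like(z, np.inf)
        r0, r1 = max(dr, 0), nrows + min(dr, 0)
        c0, c1 = max(dc, 0), ncols + min(dc, 0)
        shifted[r0 - dr: r1 - dr, c0 - dc: c1 - dc] = z[r0:r1, c0:c1]
        grad = (z - shifted) / dist
        take = grad > best_grad
        best[take] = k
        best_grad[take] = grad[take]
    return best


def _route_flats(z: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Assign directions on unresolved flats toward the nearest resolved cell.

    BFS from cells that already drain (or from the grid edge), stepping
    across equal-elevation neighbors; each flat cell points at the neighbor
    it was reached from, which yields a distance-to-lower-edge tie-break.
    """
    from collections import deque

    nrows, ncols = z.shape
    unresolved = direction < 0
    if not unresolved.any():
        return direction
    out = direction.copy()
    queue = deque()
    resolved = ~unresolved
    for r in range(nrows):
        for c in range(ncols):
            if resolved[r, c]:
                queue.append((r, c))
    seen = resolved.copy()
    while queue:
        r, c = queue.popleft()
        for k, (dr, dc) in enumerate(_D8):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and not seen[rr, cc]:
                if z[rr, cc] == z[r, c]:
                    # point the flat cell back toward (r, c)
                    out[rr, cc] = (k + 4) % 8
                    seen[rr, cc] = True
                    queue.append((rr, cc))
    return out


def flow_accumulation_d8(dtm: Raster) -> Raster:
    """D8 flow accumulation in area units (upslope cells x cell area).

    Single-cell pits are filled first; remaining flats are routed toward the
    nearest draining cell with a warning.  Every cell accumulates at least
    its own area; edge cells with no lower neighbor simply drain off-grid.
    """
    z = np.asarray(dtm.values, dtype=float)
    if z.size == 0:
        raise EmptyRasterError("empty raster")
    z = _fill_single_cell_pits(z)
    direction = _d8_directions(z, dtm.cell_size)
    interior = np.zeros_like(z, dtype=bool)
    interior[1:-1, 1:-1] = True
    if (direction[interior] < 0).any() and z.size > 1:
        warnings.warn("unresolved flats routed by distance-to-lower-edge")
        direction = _route_flats(z, direction)

    # topological (Kahn) traversal of the flow graph
    from collections import deque

    nrows, ncols = z.shape
    target = np.full(z.size, -1, dtype=np.int64)
    dirs = direction.ravel()
    rows, cols = np.divmod(np.arange(z.size), ncols)
    for k, (dr, dc) in enumerate(_D8):
        sel = dirs == k
        rr, cc = rows[sel] + dr, cols[sel] + dc
        ok = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
        tgt = np.full(sel.sum(), -1, dtype=np.int64)
        tgt[ok] = rr[ok] * ncols + cc[ok]
        target[sel] = tgt
    indeg = np.zeros(z.size, dtype=np.int64)
    np.add.at(indeg, target[target >= 0], 1)
    acc = np.ones(z.size)
    queue = deque(np.nonzero(indeg == 0)[0].tolist())
    while queue:
        idx = queue.popleft()
        t = target[idx]
        if t >= 0:
            acc[t] += acc[idx]
            indeg[t] -= 1
            if indeg[t] == 0:
                queue.append(t)
    return dtm.copy_with(acc.reshape(z.shape) * dtm.cell_size**2)


def twi(dtm: Raster, tan_beta_floor: float = 0.001) -> Raster:
    """Topographic wetness index ln(a / tan beta).

    ``a`` is the specific catchment area (flow accumulation divided by the
    cell width) and tan beta is floored at ``tan_beta_floor`` so flat cells
    stay finite.
    """
    slope, _ = slope_aspect(dtm)
    acc = flow_accumulation_d8(dtm)
    a = acc.values / dtm.cell_size
    tanb = np.maximum(np.tan(np.where(slope.values == dtm.nodata, 0.0,
                                      slope.values)), tan_beta_floor)
    return dtm.copy_with(np.log(a / tanb))


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------

def solar_position(
    latitude_deg: float,
    longitude_deg: float,
    date: _dt.date,
    local_solar_time: float,
) -> tuple[float, float]:
    """Sun elevation and azimuth (radians) at a local solar time.

    Declination delta = 23.45 deg * sin(360*(284+n)/365); elevation from
    sin h = sin phi sin delta + cos phi cos delta cos omega with hour angle
    omega = 15 deg * (t - 12).  Azimuth is clockwise from north (east in
    the morning).  Longitude is accepted for interface completeness but the
    computation is in local solar time, so no equation-of-time correction
    is applied.
    """
    if abs(latitude_deg) > 90:
        raise ValueError("latitude out of range")
    if not 0 <= local_solar_time < 24:
        raise ValueError("time must be in [0, 24)")
    n = date.timetuple().tm_yday
    decl = np.deg2rad(23.45) * np.sin(np.deg2rad(360.0 * (284 + n) / 365.0))
    phi = np.deg2rad(latitude_deg)
    omega = np.deg2rad(15.0 * (local_solar_time - 12.0))
    sin_h = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(omega)
    h = np.arcsin(np.clip(sin_h, -1.0, 1.0))
    cos_h = np.cos(h)
    if cos_h < 1e-12:
        return float(h), 0.0  # zenith: azimuth undefined
    cos_az = (np.sin(decl) - sin_h * np.sin(phi)) / (cos_h * np.cos(phi))
    az = np.arccos(np.clip(cos_az, -1.0, 1.0))
    if omega > 0:  # afternoon: sun in the west
        az = 2 * np.pi - az
    return float(h), float(az)


def clear_sky_radiation(
    dtm: Raster,
    slope: Raster,
    aspect: Raster,
    date: _dt.date,
    hours,
    latitude_deg: float = 37.42,
    longitude_deg: float = -119.6,
    transmittance: float = 0.7,
    diffuse_fraction: float = 0.15,
) -> Raster:
    """Clear-sky radiation sum over the listed hours on tilted terrain (Wh/m²).

    Per hour: direct beam = S0 * tau^(1/sin h) * cos(incidence), clamped at
    zero for self-shaded cells, plus isotropic diffuse
    S0 * tau^(1/sin h) * sin h * d_f * (1+cos s)/2.  One hourly value is
    one Wh/m² per W/m²; no topographic horizon shading.
    """
    hours = list(hours)
    s = np.where(slope.values == slope.nodata, 0.0, slope.values)
    asp = np.where(aspect.values == aspect.nodata, 0.0, aspect.values)
    total = np.zeros_like(s, dtype=float)
    any_sun = False
    for t in hours:
        h, az = solar_position(latitude_deg, longitude_deg, date, t)
        if h <= 0:
            continue
        any_sun = True
        beam = SOLAR_CONSTANT * transmittance ** (1.0 / np.sin(h))
        cos_inc = (np.cos(s) * np.sin(h)
                   + np.sin(s) * np.cos(h) * np.cos(az - asp))
        direct = beam * np.clip(cos_inc, 0.0, None)
        diffuse = beam * np.sin(h) * diffuse_fraction * (1 + np.cos(s)) / 2.0
        total += direct + diffuse
    if hours and not any_sun:
        warnings.warn("sun below horizon for all requested hours")
    return dtm.copy_with(total)
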