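"""Terrain covariates: slope, aspect, TWI and clear-sky solar radiation.

TWI = ln(a / tan beta) (a = specific catchment area from D8 routing) is a
soil-moisture proxy; the radiation surface sums hourly clear-sky
irradiance on the tilted terrain from 10:00 to 14:00 on a mid-summer day.
"""

import datetime as dt

import numpy as np

from canopymort import synthforest, terrain
from canopymort.synthforest import SceneConfig

cfg = SceneConfig(extent_m=(200.0, 200.0), cell_size_m=2.0,
                  dtm_relief=(950.0, 1050.0), seed=3)
dtm = synthforest.generate_dtm(cfg)

slope, aspect = terrain.slope_aspect(dtm)
twi = terrain.twi(dtm)
rad = terrain.clear_sky_radiation(dtm, slope, aspect, dt.date(2016, 8, 1),
                                  hours=(10, 11, 12, 13, 14),
                                  latitude_deg=37.42)

print(f"slope: mean {np.rad2deg(slope.values.mean()):.1f} deg, "
      f"max {np.rad2deg(slope.values.max()):.1f} deg")
print(f"TWI: {twi.values.min():.1f} to {twi.values.max():.1f} "
      "(high values collect upslope drainage)")
print(f"radiation 10:00-14:00: {rad.values.min():.0f}-{rad.values.max():.0f} "
      "Wh/m^2 (south-facing slopes receive the most)")
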