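"""Invert fractional vegetation cover from red/NIR reflectance.

Builds three synthetic growing-season reflectance snapshots for one year,
computes NDVI for each, composites them to the per-pixel seasonal maximum,
selects the pure-soil / pure-vegetation endpoints from sample pixels, and
applies the pixel dichotomy model.
"""

import numpy as np

from srmd.fvc import compute_fvc, compute_ndvi, max_composite, select_endpoints
from srmd.scene import SceneConfig, generate_scene

scene = generate_scene(SceneConfig(seed=0, shape=(40, 40)))
year = scene.no_mining_years[0]

ndvi_snapshots = [compute_ndvi(pair) for pair in scene.reflectance[year]]
composite = max_composite(ndvi_snapshots)

# endpoint selection from "pure" pixels: here the scene's lowest/highest
# NDVI cells stand in for hand-picked bare-soil and full-cover samples
vals = composite.valid_values()
endpoints = select_endpoints(
    pure_soil_ndvi=np.sort(vals)[:200], pure_veg_ndvi=np.sort(vals)[-200:]
)
fvc = compute_fvc(composite, endpoints)

print(f"snapshots per year:        {len(ndvi_snapshots)}")
print(f"NDVI composite range:      [{composite.min():.3f}, {composite.max():.3f}]")
print(f"selected endpoints:        NDVI_min={endpoints.ndvi_min:.3f}, "
      f"NDVI_max={endpoints.ndvi_max:.3f}")
print(f"FVC range:                 [{fvc.min():.3f}, {fvc.max():.3f}]")
print(f"mean FVC:                  {fvc.valid_values().mean():.3f}")
# The composite suppresses the per-snapshot NDVI dips (clouds / off-peak
# phenology); FVC is the fraction of each pixel covered by vegetation.
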