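"""Spatialize the five driving factors and pick the meteorological windows.

Quantifies urban and mining activity by the intensity/distance law
magnitude / (D + 1), normalizes all factors to [0, 1], and ranks candidate
month windows by the Pearson correlation between a per-year FVC summary
and the window's precipitation sum / temperature mean.
"""

import numpy as np
import pandas as pd

from srmd.drivers import distance_to_region, pearson_window_selection, quantify_activity
from srmd.scene import SceneConfig, generate_scene

scene = generate_scene(SceneConfig(seed=0, shape=(40, 40)))
year = scene.mining_years[0]
stack = scene.stacks[year]

d_mine = distance_to_region(scene.grid, scene.mine_boundary)
x_mine = quantify_activity(scene.activities[year].coal_production, d_mine)
print(f"distance to mine:     0 .. {d_mine.max():.2f} km")
print(f"raw mining intensity: {x_mine.min():.2f} .. {x_mine.max():.2f} "
      "(production / (D_M + 1))")
for fid, g in stack.factors.items():
    print(f"normalized X_{fid:<6} range [{g.min():.2f}, {g.max():.2f}]"
          + ("   <- virtual" if fid == "mine" and stack.mining_is_virtual else ""))

# window selection: which months' precipitation best explains annual FVC?
rng = np.random.default_rng(0)
years = list(range(1992, 2004))
monthly_precip = pd.DataFrame(
    rng.gamma(2.0, 20.0, (len(years), 12)), index=years, columns=range(1, 13)
)
# construct an FVC summary driven by June-August rain plus noise
fvc_summary = 0.002 * monthly_precip[[6, 7, 8]].sum(axis=1) + rng.normal(0, 0.02, len(years))
windows = [(6, 8), (7, 9), (7, 8), (1, 12), (3, 5)]
table = pearson_window_selection(fvc_summary, monthly_precip, windows, aggregate="sum")
print("\nwindow ranking by |Pearson r| (accumulated precipitation):")
print(table.to_string(index=False))
# The top-ranked window is the aggregation period used for the
# precipitation driving factor.
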