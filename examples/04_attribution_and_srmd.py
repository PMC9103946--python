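"""Identify the spatial range of mining disturbance on a synthetic scene.

The full method: calibrate the attribution noise from the no-mining years
(virtual mining factor), attribute the mining year's FVC to the mining
factor by finite differences, threshold at the noise distribution's 95%
point, and summarize the flagged region's geometry.
"""

import numpy as np

from srmd.attribution import (
    compute_contributions,
    fit_noise,
    significance_mask,
    virtual_contribution,
)
from srmd.config import StudyConfig
from srmd.gwann import train
from srmd.metrics import summarize_srmd
from srmd.scene import SceneConfig, generate_scene

scene = generate_scene(
    SceneConfig(seed=2, shape=(40, 40),
                no_mining_years=[1992, 1993, 1994, 1995], mining_years=[2020],
                mining_amplitude=0.2, mining_decay_km=1.0)
)
cfg = StudyConfig(years=scene.years, no_mining_years=scene.no_mining_years, seed=2)

# 1. attribution noise from the no-mining period
nm_stacks = {y: scene.stacks[y] for y in scene.no_mining_years}
vw = virtual_contribution(nm_stacks, scene.fvc, cfg)
samples = np.concatenate([g.valid_values() for g in vw.values()])
noise = fit_noise(samples, alpha=cfg.alpha)
print(f"virtual-contribution noise: mean={noise.mean:.4f} sd={noise.sd:.4f} "
      f"(n={noise.n})")
print(f"critical value V_0.95:      {noise.critical_value:.4f}")

# 2. mining-year attribution and significance test
year = scene.mining_years[0]
model, _ = train({year: scene.stacks[year]}, {year: scene.fvc[year]}, cfg)[year]
maps = compute_contributions(model, scene.stacks[year], cfg.bias_factor,
                             cfg.share_convention)
mask = significance_mask(maps.W["mine"], noise)
print(f"\nflagged pixels:             {mask.count()} / {mask.values.size} "
      f"({mask.values.mean():.1%})")

# 3. geometry of the identified range
if mask.count():
    res = summarize_srmd(mask, scene.mine_boundary, buffer_km=3.0)
    s = res.stats
    print(f"disturbance distance (km):  mean={s['mean']:.2f} median={s['median']:.2f} "
          f"IQR=[{s['q25']:.2f}, {s['q75']:.2f}] max={s['max']:.2f}")
    print(f"share inside 3 km buffer:   {res.buffer_fraction:.1%}")
    print(f"true disturbance radius:    {scene.truth.true_radius_km:.2f} km "
          "(suppression > 2 noise SDs)")
# Pixels whose mining contribution exceeds the noise quantile form the
# SRMD; its boundary distances and buffer containment describe how far the
# identified disturbance reaches beyond the mine.
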