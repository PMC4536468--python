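"""Sister-kinetochore oscillations and intra-kinetochore stretch.

Part 1: the axis-projected pair-center autocorrelation of a live cohort;
the lag of its first minimum estimates the oscillation half-period.
Part 2: a fixed-cell snapshot with inner (CENPA-like) and outer (HEC1-like)
kinetochore markers; δ is half the difference of the outer-outer and
inner-inner sister distances.
"""

import numpy as np

from spindlemetrics import SimConfig, analyze_cell, simulate_cell, simulate_fixed_snapshot

cfg = SimConfig(osc_amplitude_um=0.3, osc_period_s=80.0, duration_s=300.0, seed=11)
cell, _ = simulate_cell(cfg, 0)
res = analyze_cell(cell)
print(f"oscillation period simulated: {cfg.osc_period_s:.0f} s (half-period {cfg.osc_period_s/2:.0f} s)")
print(f"estimated half-period       : {res.half_period_s:.1f} s "
      f"(first AC minimum, depth {res.ac_depth:.2f})")
# the estimate lands on the 7.5-s lag grid point nearest the true half-period

snap_cfg = SimConfig(noise_sigma_um=0.020, delta_um=0.110, duration_s=7.5, seed=12)
deltas = []
for i in range(10):
    snap, _ = simulate_fixed_snapshot(snap_cfg, index=i)
    deltas.append(analyze_cell(snap).delta_um)
print(f"true intra-kinetochore delta: {snap_cfg.delta_um:.3f} um")
print(f"mean recovered delta        : {np.mean(deltas):.3f} um over {len(deltas)} cells")
# 20-nm localization noise leaves the mean estimate within a few nm of truth
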