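"""Motility metrics of microglial process tips converging on a lesion.

Generates jittered tip trajectories for two path classes — through open
neuropil (slower, shorter paths) and around cell bodies (faster, longer
detours) — and computes each tip's cumulative distance to arrival and its
mean velocity over the early linear portion of the approach (frames 3-7).
"""

import numpy as np

from shadowimg.microglia import track_metrics, trajectories_from_table
from shadowimg.phantoms import PhantomConfig, make_trajectories

table, truth = make_trajectories(PhantomConfig(seed=5))

by_class = {}
for traj in trajectories_from_table(table.frame, lesion_point_um=(0.0, 0.0)):
    m = track_metrics(traj, arrival_radius_um=2.0)
    by_class.setdefault(traj.path_class, []).append(m)

for cls, ms in by_class.items():
    v = np.mean([m.mean_velocity_um_s for m in ms])
    d = np.mean([m.cumulative_distance_um for m in ms])
    print(f"{cls:12s}: n = {len(ms):2d}, mean velocity = {v:.3f} µm/s, "
          f"mean cumulative distance = {d:.1f} µm")
print("tips detouring around cell bodies move faster but travel farther —")
print("the velocity/distance split separates the two navigation strategies.")
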