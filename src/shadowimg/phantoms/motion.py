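"""Process-tip trajectories and dye-clearance time courses.

Trajectories emulate manually tracked microglial process tips converging
on a laser lesion: each tip advances toward the lesion point at a constant
nominal speed, with isotropic Gaussian positional jitter emulating
tracking error, until its cumulative nominal path equals the configured
path length, then dwells at the lesion for a few frames. Two path classes
are generated — tips moving through open neuropil and tips detouring
around cell bodies (faster, over longer paths).

Clearance series are noiseless or noisy samples of I(t) = I0 exp(-lambda t);
when a target fractional drop d over [t1, t2] is configured, the decay
constant is lambda = ln(1/(1-d)) / (t2 - t1), so the generated series
reproduces that drop exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import MeasurementTable
from .config import GroundTruth, PhantomConfig, TrajectoryRecord

__all__ = ["make_trajectories", "make_clearance_series"]


def make_trajectories(config: PhantomConfig) -> tuple[MeasurementTable, GroundTruth]:
    """Generate jittered tip trajectories for both path classes.

    Returns a table with columns (tip_id, path_class, frame, t_s, y_um,
    x_um) — frame is 0-based — plus per-tip ground-truth records. With
    zero jitter the per-frame displacement is exactly speed * dt until the
    final (possibly partial) step onto the lesion point.
    """
    tc = config.trajectories
    rng = config.rng("trajectories")
    lesion = (0.0, 0.0)
    rows = []
    records = []
    tip_id = 0
    for cls_name in ("neuropil", "cell_bodies"):
        cls = getattr(tc, cls_name)
        step = cls.speed_um_s * tc.dt_s
        n_steps = int(np.ceil(cls.path_length_um / step))
        for _ in range(cls.n_tips):
            ang = rng.uniform(0, 2 * np.pi)
            u = np.array([np.sin(ang), np.cos(ang)])
            # tips halt at the lesion-core boundary: total travel is exactly
            # path_length, ending lesion_core_radius short of the centre
            start = np.array(lesion) + (cls.path_length_um + tc.lesion_core_radius_um) * u
            nominal = [start - min(k * step, cls.path_length_um) * u
                       for k in range(n_steps + 1)]
            nominal += [nominal[-1]] * tc.dwell_frames  # tip dwells at the core edge
            for k, p in enumerate(nominal):
                jit = rng.normal(0.0, tc.jitter_sigma_um, 2) if tc.jitter_sigma_um > 0 else 0.0
                q = p + jit
                rows.append({
                    "tip_id": tip_id, "path_class": cls_name, "frame": k,
                    "t_s": k * tc.dt_s, "y_um": float(q[0]), "x_um": float(q[1]),
                })
            records.append(TrajectoryRecord(
                tip_id=tip_id, path_class=cls_name, speed_um_s=cls.speed_um_s,
                path_length_um=cls.path_length_um, lesion_point_um=lesion,
            ))
            tip_id += 1
    table = MeasurementTable(
        pd.DataFrame(rows), operation="make_trajectories",
        params={"dt_s": tc.dt_s, "jitter_sigma_um": tc.jitter_sigma_um,
                "lesion_point_um": lesion},
    )
    return table, GroundTruth(trajectory_records=records)


def make_clearance_series(config: PhantomConfig) -> MeasurementTable:
    """Sampled exponential dye-clearance intensity time course."""
    cc = config.clearance
    lam = cc.decay_constant()
    t = np.arange(cc.t_start_h, cc.t_end_h + 1e-9, cc.dt_h)
    i = cc.i0 * np.exp(-lam * t)
    if cc.noise_sd > 0:
        i = np.clip(i + config.rng("clearance").normal(0, cc.noise_sd, i.shape), 0, None)
    df = pd.DataFrame({"time_h": t, "intensity": i})
    return MeasurementTable(df, operation="make_clearance_series",
                            params={"decay_per_hour": lam, "i0": cc.i0})
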