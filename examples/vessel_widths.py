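"""Measure vessel-lumen and perivascular-space widths and their coupling.

Simulates 150 capillary cross-sections (dark lumen flanked by bright
perivascular stripes), fits the composite two-peak/one-trough model to an
orthogonal profile of each, and reports the population means and the
Pearson correlation between lumen diameter and PVS width.
"""

import numpy as np

from shadowimg.phantoms import PhantomConfig, VesselConfig, make_vessel_phantom
from shadowimg.vasculature import (
    VesselAxis,
    measure_vessel_cross_section,
    place_orthogonal_profiles,
    pvs_vessel_correlation,
)

cfg = PhantomConfig(seed=3, vessel=VesselConfig(n_vessels=150))
stack, truth = make_vessel_phantom(cfg)

measurements = []
for rec in truth.vessel_records:
    axis = VesselAxis(np.array(rec.axis_points_um), rec.label)
    stations = place_orthogonal_profiles(stack, axis, spacing_um=10.0,
                                         half_length_um=6.5, t=rec.frame)
    measurements.append(measure_vessel_cross_section(stations[0][1], rec.label))

ok = [m for m in measurements if m.quality == "ok"]
lumen = np.mean([m.lumen_fwhm_um for m in ok])
pvs = np.mean([m.pvs_mean_um for m in ok])
corr = pvs_vessel_correlation(ok)

print(f"measured {len(ok)} vessels")
print(f"mean lumen FWHM     = {lumen:.2f} µm   (generated around 3.7 µm)")
print(f"mean PVS FWHM       = {pvs:.3f} µm  (generated around 0.58 µm)")
print(f"lumen-PVS Pearson r = {corr.r:.3f} (p = {corr.p:.2g}, n = {corr.n})")
print("wider vessels carry wider perivascular spaces; r quantifies that coupling.")
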