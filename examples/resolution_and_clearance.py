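"""Bead-based resolution measurement and dye-clearance kinetics.

Measures the lateral point-spread FWHM from a simulated field of
sub-diffraction beads, then computes the fractional intensity drop of an
exponential dye-clearance time course between 1 h and 4 h.
"""

from shadowimg.phantoms import (
    BeadConfig,
    NoiseConfig,
    PhantomConfig,
    make_bead_field,
    make_clearance_series,
)
from shadowimg.profiles import intensity_drop, measure_bead_resolution

cfg = PhantomConfig(seed=7, field_shape=(1000, 1000), dx_um=0.04,
                    noise=NoiseConfig(photon_peak=500),
                    beads=BeadConfig(n_beads=50, fwhm_um=0.212))
stack, truth = make_bead_field(cfg)
table = measure_bead_resolution(stack)
print(f"{table.params['n_beads']} beads, "
      f"mean lateral FWHM = {1000 * table.params['mean_fwhm_um']:.0f} nm "
      f"(generated at {1000 * cfg.beads.fwhm_um:.0f} nm)")
print("the bead FWHM is the system's effective lateral resolution.")

series = make_clearance_series(PhantomConfig(seed=1))
drop = intensity_drop(series.frame, t1=1.0, t2=4.0)
print(f"\ndye intensity drop between 1 h and 4 h: {drop:.1f}%")
print("labeling decays as the dye clears, but stays workable for hours —")
print("the drop quantifies the usable imaging window after an injection.")
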