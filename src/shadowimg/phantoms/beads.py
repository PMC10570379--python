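"""Fluorescent-bead field for lateral-resolution measurement.

Sub-diffraction beads image as 2-D Gaussian spots whose FWHM is the
system's lateral resolution. Spots are placed at random sub-pixel
positions with a minimum mutual separation (and a border margin wide
enough for profile fitting), rendered analytically at the configured
image-domain FWHM, then passed through the detection-noise model.
"""

from __future__ import annotations

import numpy as np

from ..core import ImageStack, PixelGeometry
from .config import BeadRecord, GroundTruth, PhantomConfig
from .optics import apply_psf_noise
from ..profiles import FWHM_PER_SIGMA

__all__ = ["make_bead_field"]


def make_bead_field(config: PhantomConfig) -> tuple[ImageStack, GroundTruth]:
    bc = config.beads
    dx = config.dx_um
    rng = config.rng("beads")
    ny, nx = config.field_shape
    margin_um = max(1.5, 4 * bc.fwhm_um)

    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < bc.n_beads:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place the requested beads at the "
                               "configured separation; enlarge the field")
        y = rng.uniform(margin_um, (ny - 1) * dx - margin_um)
        x = rng.uniform(margin_um, (nx - 1) * dx - margin_um)
        if all((y - py) ** 2 + (x - px) ** 2 >= bc.min_separation_um**2
               for py, px in positions):
            positions.append((y, x))

    img = np.full((ny, nx), bc.background)
    sigma = bc.fwhm_um / FWHM_PER_SIGMA
    half = int(np.ceil(5 * sigma / dx))
    records = []
    for i, (y, x) in enumerate(positions):
        iy, ix = int(round(y / dx)), int(round(x / dx))
        ys = np.arange(max(0, iy - half), min(ny, iy + half + 1))
        xs = np.arange(max(0, ix - half), min(nx, ix + half + 1))
        gy = np.exp(-0.5 * ((ys * dx - y) / sigma) ** 2)
        gx = np.exp(-0.5 * ((xs * dx - x) / sigma) ** 2)
        img[np.ix_(ys, xs)] += bc.amplitude * gy[:, None] * gx[None, :]
        records.append(BeadRecord(bead_id=i, y_um=y, x_um=x, fwhm_um=bc.fwhm_um))

    clean = ImageStack(img, geometry=PixelGeometry(dx=dx))
    stack = apply_psf_noise(clean, 0.0, config.noise, seed=config.rng("beads-noise"))
    return stack, GroundTruth(bead_records=records)
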