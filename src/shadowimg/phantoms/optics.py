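"""Image formation: Gaussian PSF blur and shot/read noise.

The optical transfer of the modeled systems is approximated by a 2-D
Gaussian point-spread function (sigma = FWHM / (2 sqrt(2 ln 2))), applied
per (t, c, z) plane with reflective boundaries so that the spatial mean is
conserved. Detection noise is the minimal realistic photon-counting model:
Poisson shot noise at a configurable photons-per-unit-intensity scaling
plus additive Gaussian read noise; the returned image is rescaled back to
intensity units, so the expected value equals the noiseless input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..core import ImageStack
from .config import NoiseConfig
from ..profiles import FWHM_PER_SIGMA

__all__ = ["apply_psf_noise", "blur_plane"]


def blur_plane(plane: np.ndarray, fwhm_um: float, dx_um: float) -> np.ndarray:
    """Convolve one (y, x) plane with a unit-sum Gaussian of the given FWHM."""
    if fwhm_um <= 0:
        return plane.astype(float, copy=True)
    sigma_px = fwhm_um / FWHM_PER_SIGMA / dx_um
    return ndimage.gaussian_filter(plane.astype(float), sigma_px, mode="reflect")


def apply_psf_noise(
    stack: ImageStack,
    psf_fwhm_xy_um: float,
    noise: NoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> ImageStack:
    """Blur every plane, then add Poisson + Gaussian detection noise.

    Zero FWHM is the identity; a zero-noise config gives a pure blur.
    The output is clipped at zero (counts cannot be negative after read
    noise) and returned in the input's intensity units.
    """
    if psf_fwhm_xy_um < 0:
        raise ValueError("psf_fwhm_xy_um must be >= 0")
    noise = noise or NoiseConfig(photon_peak=0.0, read_sigma=0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    data = stack.data.astype(float)
    out = np.empty_like(data)
    T, C, Z = data.shape[:3]
    for t in range(T):
        for c in range(C):
            for z in range(Z):
                out[t, c, z] = blur_plane(data[t, c, z], psf_fwhm_xy_um, stack.geometry.dx)

    if noise.photon_peak > 0:
        out = rng.poisson(noise.photon_peak * out).astype(float)
        if noise.read_sigma > 0:
            out += rng.normal(0.0, noise.read_sigma, out.shape)
        out /= noise.photon_peak
    elif noise.read_sigma > 0:
        out += rng.normal(0.0, noise.read_sigma, out.shape)
    np.clip(out, 0.0, None, out=out)
    return stack.copy_with(out, normalized=False, saturated=None)
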