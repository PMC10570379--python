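"""Neuropil phantom: inverted-contrast tissue at a known ECS volume fraction.

The extracellular space (ECS) is the labeled, bright phase; cells and
neurites are dark silhouettes. The generator packs randomly oriented
elliptical cell/neurite cross-sections into the field until the remaining
bright fraction matches the requested volume fraction, reserves a
rectangular pure-ECS plateau (emulating a large perivascular or surface
pool used as the normalization reference), then applies the PSF/noise
image-formation model. The pre-blur binary mask and the achieved fraction
are returned as ground truth.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import ellipse

from ..core import ImageStack, PixelGeometry, RoiMask
from .config import GroundTruth, PhantomConfig
from .optics import apply_psf_noise

__all__ = ["make_neuropil_phantom", "random_neuropil_rois", "plateau_reference_roi"]

#: volume-fraction calibration tolerance of the generator
VF_TOL = 0.002


def make_neuropil_phantom(config: PhantomConfig) -> tuple[ImageStack, GroundTruth]:
    """Generate a single-plane shadow image of neuropil at ``config.vf_true``.

    The binary tissue geometry (ECS = 1, cells = 0) is built by packing
    rounded cell-body and neurite cross-sections; a final pixel-level
    adjustment brings the ECS pixel fraction within +/-0.002 of the target
    (single-pixel granularity disappears under the PSF). The pure-ECS
    plateau has a minimum side of at least 3x the lateral PSF FWHM so its
    interior survives blurring unchanged.
    """
    vf = config.vf_true
    ny, nx = config.field_shape
    dx = config.dx_um
    rng = config.rng("neuropil")

    ecs = np.ones((ny, nx), bool)

    # pure-ECS plateau in the top-left corner, side >= max(3*PSF, 4 um)
    side_um = max(3.0 * config.psf_fwhm_xy_um, 2.0)
    side = int(np.ceil(side_um / dx))
    margin = int(np.ceil(max(config.psf_fwhm_xy_um, dx) / dx))
    y0, x0 = margin, margin
    plateau = (y0, y0 + side, x0, x0 + side)
    # only the plateau itself is protected; the reference ROI is eroded at
    # measurement time, so structures may abut the plateau edge
    protect = np.zeros((ny, nx), bool)
    protect[y0:y0 + side, x0:x0 + side] = True

    # pack neurite-scale elliptical cross-sections; the neuropil proper is a
    # fine feltwork of sub-µm processes, so structures stay small — this is
    # what keeps the ECS fraction spatially homogeneous at the ~10 µm ROI
    # scale, as in tissue where VF regions avoid cell bodies
    total = ecs.size
    max_draws = 500_000
    draws = 0
    n_ecs = int(ecs.sum())
    a_max_um = 0.6
    while n_ecs > (vf + VF_TOL) * total and draws < max_draws:
        draws += 1
        a_um = rng.uniform(0.15, a_max_um)
        b_um = rng.uniform(0.1, a_um)
        # centres extend beyond the field so border coverage stays uniform
        pad = a_max_um / dx
        cy, cx = rng.uniform(-pad, ny + pad), rng.uniform(-pad, nx + pad)
        rr, cc = ellipse(cy, cx, a_um / dx, b_um / dx,
                         shape=(ny, nx), rotation=rng.uniform(0, np.pi))
        keep = ~protect[rr, cc] & ecs[rr, cc]
        n_ecs -= int(keep.sum())
        ecs[rr[keep], cc[keep]] = False
    if n_ecs > (vf + VF_TOL) * total:
        raise RuntimeError(
            f"could not reach vf_true={vf} after {max_draws} structure draws"
        )

    # pixel-level calibration to the exact target fraction, computed over the
    # region ROIs can sample (outside the protected plateau, which is forced
    # ECS and would otherwise bias every neuropil ROI low)
    free = ~protect.ravel()
    ecs_flat = ecs.ravel()
    deficit = int(round(vf * free.sum())) - int(ecs_flat[free].sum())
    if deficit > 0:      # too few ECS pixels: return random cell pixels to ECS
        idx = np.flatnonzero(free & ~ecs_flat)
        flip = rng.choice(idx, size=min(deficit, idx.size), replace=False)
        ecs_flat[flip] = True
    elif deficit < 0:    # too many: convert random free ECS pixels to cell
        idx = np.flatnonzero(free & ecs_flat)
        flip = rng.choice(idx, size=min(-deficit, idx.size), replace=False)
        ecs_flat[flip] = False

    geometry = PixelGeometry(dx=dx, dz=config.dz_um)
    clean = ImageStack(ecs.astype(float), geometry=geometry)
    stack = apply_psf_noise(clean, config.psf_fwhm_xy_um, config.noise,
                            seed=config.rng("neuropil-noise"))
    truth = GroundTruth(
        ecs_mask=RoiMask(ecs, label="ecs_truth"),
        cell_body_mask=RoiMask(~ecs, label="cells_truth", allow_empty=True),
        pure_ecs_rect=plateau,
        achieved_vf=float(ecs.mean()),
    )
    return stack, truth


def plateau_reference_roi(truth: GroundTruth, erosion_px: int = 5) -> RoiMask:
    """Pure-ECS reference ROI: the plateau interior, eroded so that blur
    bleeding in from surrounding structures does not contaminate it."""
    y0, y1, x0, x1 = truth.pure_ecs_rect
    if y1 - y0 <= 2 * erosion_px or x1 - x0 <= 2 * erosion_px:
        raise ValueError("plateau too small for the requested erosion")
    m = np.zeros(truth.ecs_mask.mask.shape, bool)
    m[y0 + erosion_px:y1 - erosion_px, x0 + erosion_px:x1 - erosion_px] = True
    return RoiMask(m, label="pure_ecs_plateau")


def random_neuropil_rois(
    truth: GroundTruth,
    n: int,
    size_um: float,
    dx_um: float,
    rng: np.random.Generator | int = 0,
) -> list[RoiMask]:
    """Place ``n`` random square neuropil ROIs that avoid the pure-ECS plateau.

    Emulates the manual placement of analysis regions in neuropil; ROIs may
    overlap one another but never the reference plateau.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ny, nx = truth.ecs_mask.mask.shape
    side = max(2, int(round(size_um / dx_um)))
    py0, py1, px0, px1 = truth.pure_ecs_rect
    rois = []
    attempts = 0
    while len(rois) < n:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place the requested ROIs off-plateau")
        y = rng.integers(0, ny - side)
        x = rng.integers(0, nx - side)
        if y < py1 and y + side > py0 and x < px1 and x + side > px0:
            continue  # overlaps the reference plateau
        m = np.zeros((ny, nx), bool)
        m[y:y + side, x:x + side] = True
        rois.append(RoiMask(m, label=f"neuropil_{len(rois):02d}"))
    return rois
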