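"""ECS volume-fraction estimation from normalized shadow-image intensity.

In a shadow image the extracellular dye fills only the extracellular
space, so the fluorescence collected from a neuropil voxel is proportional
to the fraction of that voxel occupied by ECS. The volume fraction of a
region is therefore

    VF = (mean ROI intensity - background) / (I_ECS - background)

where I_ECS is the signal from a region of pure ECS (a perivascular pool
or, as a fallback, the brightest pixels of the field). Because spatial
averaging commutes with the optical blur, the estimate is independent of
the microscope's resolution — the key property that lets a
diffraction-limited system report a sub-resolution quantity.

The background term defaults to zero: the estimator mirrors the plain
normalized-intensity formula, with an optional detector-offset term for
instruments that need it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageStack, RoiMask

__all__ = ["VFEstimate", "estimate_pure_ecs_intensity", "estimate_vf", "summarize_vf"]


@dataclass
class VFEstimate:
    roi_label: str
    mean_intensity: float
    ecs_reference: float
    background: float
    vf: float
    clipped: bool = False


def _spatial_planes(stack: ImageStack, t: int = 0, c: int = 0) -> np.ndarray:
    """(z, y, x) view of one timepoint/channel."""
    return stack.data[t, c]


def _apply_mask(vol: np.ndarray, roi: RoiMask) -> np.ndarray:
    if roi.mask.ndim == 2:
        return vol[:, roi.mask].ravel()
    if roi.mask.shape != vol.shape:
        raise ValueError("3-D ROI shape does not match the stack's (z,y,x) axes")
    return vol[roi.mask]


def estimate_pure_ecs_intensity(
    stack: ImageStack,
    reference: RoiMask | None = None,
    top_fraction: float = 0.001,
    t: int = 0,
    c: int = 0,
) -> float:
    """Estimate the pure-ECS reference intensity.

    ROI mode (a designated perivascular/pure-ECS region) takes the mean of
    the ROI pixels and refuses regions containing saturated pixels — the
    normalization is only valid with the detector in its linear range.
    Top-fraction mode (default top 0.1% of the field) approximates pure
    ECS by the brightest pixels of the field of view.
    """
    vol = _spatial_planes(stack, t, c)
    if reference is not None:
        if stack.saturated is not None:
            sat = _apply_mask(stack.saturated[t, c], reference)
            if sat.any():
                raise ValueError(
                    f"reference ROI {reference.label!r} contains saturated pixels"
                )
        return float(_apply_mask(vol, reference).mean())
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    flat = np.sort(vol.ravel())
    k = max(1, int(round(top_fraction * flat.size)))
    return float(flat[-k:].mean())


def estimate_vf(
    stack: ImageStack,
    neuropil_rois: list[RoiMask],
    reference: RoiMask | None = None,
    top_fraction: float = 0.001,
    background: float | RoiMask = 0.0,
    t: int = 0,
    c: int = 0,
) -> list[VFEstimate]:
    """Volume-fraction estimate for each neuropil ROI.

    ``background`` may be a fixed offset (default 0, mirroring the plain
    normalized-intensity formula) or a dark ROI whose mean is subtracted.
    Estimates outside [0, 1] — possible under noise — are clipped and
    flagged rather than rejected.
    """
    if not neuropil_rois:
        raise ValueError("need at least one neuropil ROI")
    i_ecs = estimate_pure_ecs_intensity(stack, reference, top_fraction, t, c)
    vol = _spatial_planes(stack, t, c)
    bg = (float(_apply_mask(vol, background).mean())
          if isinstance(background, RoiMask) else float(background))
    if bg >= i_ecs:
        raise ValueError(f"background ({bg}) must be below the ECS reference ({i_ecs})")
    out = []
    for roi in neuropil_rois:
        mean_i = float(_apply_mask(vol, roi).mean())
        vf = (mean_i - bg) / (i_ecs - bg)
        clipped = not (0.0 <= vf <= 1.0)
        out.append(VFEstimate(
            roi_label=roi.label, mean_intensity=mean_i, ecs_reference=i_ecs,
            background=bg, vf=float(np.clip(vf, 0.0, 1.0)), clipped=clipped,
        ))
    return out


def summarize_vf(estimates: list[VFEstimate]) -> tuple[float, float, int]:
    """Group mean and SEM of the VF estimates, in percent.

    A single estimate has no dispersion; its SEM is reported as 0.
    """
    if not estimates:
        raise ValueError("no estimates to summarize")
    vals = np.array([e.vf for e in estimates]) * 100.0
    n = len(vals)
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(vals.mean()), sem, n
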