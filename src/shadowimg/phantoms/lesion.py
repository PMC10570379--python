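"""Two-channel laser-lesion time series with phagocytic cups.

Channel 0 emulates EGFP-labeled microglia: bright ring-shaped phagocytic
cups (annuli with dark interiors) plus open arcs and line segments as
non-cup distractors. Channel 1 is the raw shadow channel: bright dye-filled
extracellular background, dark (dye-negative) intact structures, and a
central lesion where lysed (dye-positive) material is as bright as or
brighter than the background while intact blebbing material stays dark.

Each cup interior is painted according to its drawn content class:
lysed-class interiors are dye-bright for the cup's whole lifetime,
intact-class interiors dye-dark, and "both"-class interiors switch from
lysed to intact halfway through (contents are engulfed sequentially), so
the downstream median-content rule sees each state clearly in at least
some frames. Cups are laid out on a jittered grid so their interiors can
never merge, and appear from frame 2 onward, leaving frames 0-1 as a
clean pre-lesion baseline.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk, ellipse, line

from ..core import ImageStack, PixelGeometry
from .config import CupRecord, GroundTruth, PhantomConfig
from .optics import apply_psf_noise

__all__ = ["make_lesion_series", "draw_cup_classes"]

#: grid pitch between cup slots, µm
SLOT_UM = 10.0
#: raw shadow-channel intensities
BG_SHADOW = 0.4
LYSED_VAL = 1.0
INTACT_VAL = 0.0


def draw_cup_classes(
    n_cups: int,
    probs: tuple[float, float, float],
    rng: np.random.Generator,
    exact_counts: bool = False,
) -> list[str]:
    """Assign content classes; exact_counts forces the largest-remainder split."""
    names = ["lysed", "intact", "both"]
    if exact_counts:
        raw = [p * n_cups for p in probs]
        counts = [int(np.floor(r)) for r in raw]
        rem = n_cups - sum(counts)
        order = np.argsort([c - r for c, r in zip(counts, raw)])
        for i in range(rem):
            counts[order[i]] += 1
        classes = sum(([names[i]] * counts[i] for i in range(3)), [])
        rng.shuffle(classes)
        return classes
    draws = rng.choice(3, size=n_cups, p=list(probs))
    return [names[i] for i in draws]


def make_lesion_series(config: PhantomConfig) -> tuple[ImageStack, GroundTruth]:
    lc = config.lesion
    dx = lc.dx_um
    rng = config.rng("lesion")
    noise = config.noise.model_copy(update={"photon_peak": lc.photon_peak})

    # field sized so every cup gets its own grid slot (plus distractor slots)
    n_slots = max(lc.n_cups + 8, 16)
    ncols = int(np.ceil(np.sqrt(n_slots)))
    nrows = int(np.ceil(n_slots / ncols))
    slot_px = int(round(SLOT_UM / dx))
    ny, nx = nrows * slot_px, ncols * slot_px
    T = lc.n_frames

    egfp = np.full((T, ny, nx), 0.05)
    shadow = np.full((T, ny, nx), BG_SHADOW)
    lesion_mask = np.zeros((T, ny, nx), bool)

    slots = [(r, c) for r in range(nrows) for c in range(ncols)]
    rng.shuffle(slots)
    classes = draw_cup_classes(lc.n_cups, lc.content_probs, rng, lc.exact_counts)

    # static intact structures outside the lesion event (normal dark cells)
    for _ in range(max(4, n_slots // 20)):
        cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
        rr, cc = ellipse(cy, cx, rng.uniform(6, 12), rng.uniform(4, 10),
                         shape=(ny, nx), rotation=rng.uniform(0, np.pi))
        shadow[:, rr, cc] = INTACT_VAL

    cup_records = []
    for cup_id, cls in enumerate(classes):
        r, c = slots[cup_id]
        cy = (r + 0.5) * slot_px + rng.uniform(-1.0, 1.0) / dx
        cx = (c + 0.5) * slot_px + rng.uniform(-1.0, 1.0) / dx
        d_in = float(np.clip(rng.normal(lc.cup_diameter_um, lc.cup_diameter_sd_um),
                             4.5, 7.5))
        r_in = d_in / 2.0 / dx
        r_out = r_in + 1.0 / dx  # 1 µm ring thickness
        f0 = int(rng.integers(2, 4))
        f1 = T - 1
        ring_rr, ring_cc = disk((cy, cx), r_out, shape=(ny, nx))
        hole_rr, hole_cc = disk((cy, cx), r_in, shape=(ny, nx))
        mid = (f0 + f1) // 2
        for t in range(f0, f1 + 1):
            egfp[t, ring_rr, ring_cc] = 1.0
            egfp[t, hole_rr, hole_cc] = 0.0
            if cls == "lysed" or (cls == "both" and t <= mid):
                val = LYSED_VAL
            else:
                val = INTACT_VAL
            shadow[t, hole_rr, hole_cc] = val
            lesion_mask[t, hole_rr, hole_cc] = True
        cup_records.append(CupRecord(
            cup_id=cup_id, content_class=cls,
            centroid_um=(cy * dx, cx * dx),
            interior_diameter_um=d_in, frame_start=f0, frame_end=f1,
        ))

    # non-cup distractors in unused slots: arcs (open rings) and segments
    spare = slots[lc.n_cups:]
    for k, (r, c) in enumerate(spare[: max(4, len(spare) // 2)]):
        cy, cx = (r + 0.5) * slot_px, (c + 0.5) * slot_px
        if k % 2 == 0:
            th = np.linspace(0.3, 2 * np.pi - 1.2, 200)  # C-shape: gap stays open
            rad = 3.0 / dx
            for width in np.linspace(rad, rad + 1.0 / dx, 6):
                rr = np.clip((cy + width * np.sin(th)).astype(int), 0, ny - 1)
                cc = np.clip((cx + width * np.cos(th)).astype(int), 0, nx - 1)
                egfp[2:, rr, cc] = 1.0
        else:
            ang = rng.uniform(0, np.pi)
            dy, dun = np.sin(ang) * 3.5 / dx, np.cos(ang) * 3.5 / dx
            rr, cc = line(int(cy - dy), int(cx - dun), int(cy + dy), int(cx + dun))
            keep = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
            egfp[2:, rr[keep], cc[keep]] = 1.0

    # lesion-area debris growing around the field centre: micron-scale lysed
    # pools and dark intact blebs appearing from frame 2 onward
    lcy, lcx = ny / 2.0, nx / 2.0
    n_blobs = max(6, n_slots // 12)
    blob_t0 = rng.integers(2, T - 1, n_blobs)
    blob_pos = rng.normal((lcy, lcx), 2.5 / dx, (n_blobs, 2))
    blob_rad = rng.uniform(0.8, 1.5, n_blobs) / dx
    blob_lysed = rng.random(n_blobs) < 0.6
    for i in range(n_blobs):
        rr, cc = disk(tuple(blob_pos[i]), blob_rad[i], shape=(ny, nx))
        untouched = shadow[blob_t0[i], rr, cc] == BG_SHADOW
        rr, cc = rr[untouched], cc[untouched]
        for t in range(int(blob_t0[i]), T):
            shadow[t, rr, cc] = LYSED_VAL if blob_lysed[i] else INTACT_VAL
            lesion_mask[t, rr, cc] = True

    data = np.stack([egfp, shadow], axis=1)[:, :, None]  # (t, c, z=1, y, x)
    geometry = PixelGeometry(dx=dx, dt=lc.dt_s)
    clean = ImageStack(data, geometry=geometry)
    stack = apply_psf_noise(clean, config.psf_fwhm_xy_um, noise,
                            seed=config.rng("lesion-noise"))
    truth = GroundTruth(cup_records=cup_records, lesion_masks=lesion_mask)
    return stack, truth
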