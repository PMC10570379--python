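"""Microglial lesion-response pipeline: triage and motility.

After a focal laser lesion, microglia extend processes toward the damage
and engulf material in cup-shaped structures ("phagocytic cups") at their
process tips. Two-channel time series drive the analysis:

* the shadow channel (dye-filled extracellular space) distinguishes lysed
  material — membrane-compromised, dye-positive, bright — from intact
  material — dye-excluding, dark;
* the EGFP channel shows the microglia themselves; a phagocytic cup
  encloses its cargo, so in a binarized frame it appears as a hole, and
  filling holes and subtracting the original binary image yields exactly
  the candidate cup interiors.

The triage question is whether microglia preferentially engulf lysed over
intact material: cup interiors are classified by redirecting them onto the
thresholded shadow masks (a cup is positive for a state when more than
half of its interior pixels carry it — the median of the binary content
is non-zero), and enrichment compares the state composition inside cups
("In PC") with the composition of the developing lesion area ("In ROI").

Motility metrics summarize manually tracked process-tip trajectories:
cumulative distance traveled until arrival at the lesion, and the mean
velocity over the early linear portion of the approach (frames 3-7,
1-based), split by whether the straight path to the lesion crosses a cell
body or only neuropil.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import disk

from .core import ImageStack, invert, normalize_frame

__all__ = [
    "TriageParams",
    "PhagocyticCup",
    "TriageSummary",
    "TipTrajectory",
    "MotilityMetrics",
    "preprocess_coshi",
    "threshold_tissue_state",
    "detect_lesion_roi",
    "detect_phagocytic_cups",
    "classify_cup_contents",
    "enrichment_stats",
    "track_metrics",
    "classify_path",
    "trajectories_from_table",
]


@dataclass
class TriageParams:
    """Tunable parameters of the triage pipeline.

    The thresholds are fractions of the per-frame robust-normalized range
    of the inverted shadow image: intact (dye-negative) structures are
    pixels strictly above ``intact_threshold``, lysed (dye-positive)
    strictly below ``lysed_threshold``. The cup gates operationalize
    "circular structures within the size range of phagocytic cups":
    a hard equivalent-diameter window centred on the typical ~6 µm cup,
    a circularity floor, and circularity ranking of survivors.
    """

    median_radius_px: int = 4
    intact_threshold: float = 0.70
    lysed_threshold: float = 0.02
    cup_diameter_range_um: tuple[float, float] = (3.0, 12.0)
    min_circularity: float = 0.6
    binarize: str = "otsu"          # or "fixed"
    binarize_threshold: float = 0.5  # used when binarize == "fixed"
    close_radius_um: float = 1.0
    arrival_radius_um: float = 2.0
    velocity_frames: tuple[int, int] = (3, 7)  # 1-based inclusive window
    cell_body_min_diameter_um: float = 5.0

    def __post_init__(self):
        if not 0 <= self.lysed_threshold < self.intact_threshold <= 1:
            raise ValueError("need 0 <= lysed_threshold < intact_threshold <= 1")
        lo, hi = self.cup_diameter_range_um
        if not 0 < lo < hi:
            raise ValueError("cup_diameter_range_um must be positive and ordered")


@dataclass
class PhagocyticCup:
    cup_id: int
    frames: list[int]
    footprints: dict = field(repr=False, default_factory=dict)  # frame -> (rr, cc)
    centroids_um: dict = field(default_factory=dict)
    areas_um2: dict = field(default_factory=dict)
    eq_diameters_um: dict = field(default_factory=dict)
    circularities: dict = field(default_factory=dict)
    content_class: str = "unclassified"
    positive_lysed_frames: list[int] = field(default_factory=list)
    positive_intact_frames: list[int] = field(default_factory=list)

    @property
    def mean_circularity(self) -> float:
        return float(np.mean(list(self.circularities.values())))

    @property
    def median_diameter_um(self) -> float:
        return float(np.median(list(self.eq_diameters_um.values())))


@dataclass
class TriageSummary:
    n_cups: int
    percent_lysed: float
    percent_intact: float
    percent_both: float
    percent_empty: float
    in_roi_lysed: float | None = None
    in_roi_intact: float | None = None
    in_pc_lysed: float | None = None
    in_pc_intact: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_cups", "percent_lysed", "percent_intact", "percent_both",
            "percent_empty", "in_roi_lysed", "in_roi_intact",
            "in_pc_lysed", "in_pc_intact")}


@dataclass
class TipTrajectory:
    frames: np.ndarray          # 0-based, strictly increasing
    t_s: np.ndarray
    y_um: np.ndarray
    x_um: np.ndarray
    lesion_point_um: tuple[float, float]
    tip_id: int = 0
    path_class: str = "unassigned"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, int)
        if (np.diff(self.frames) <= 0).any():
            raise ValueError("trajectory frames must be strictly increasing")
        self.t_s = np.asarray(self.t_s, float)
        self.y_um = np.asarray(self.y_um, float)
        self.x_um = np.asarray(self.x_um, float)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.y_um, self.x_um])


@dataclass
class MotilityMetrics:
    cumulative_distance_um: float
    mean_velocity_um_s: float | None
    arrival_frame: int | None


# ---------------------------------------------------------------------------
# Shadow-channel preprocessing and tissue-state masks


def preprocess_coshi(stack: ImageStack, params: TriageParams | None = None) -> ImageStack:
    """Median-filter, robust-normalize and invert the shadow channel.

    The median filter (disk neighbourhood, default radius 4 px) suppresses
    shot noise without eroding structure edges the way a linear blur
    would; per-frame normalization then maps the stated fractional
    thresholds onto a stable [0, 1] range, and inversion makes cellular
    structures bright.
    """
    params = params or TriageParams()
    foot = disk(params.median_radius_px)
    out = np.empty_like(stack.data, dtype=float)
    T, C, Z = stack.shape[:3]
    for t in range(T):
        for c in range(C):
            for z in range(Z):
                out[t, c, z] = ndimage.median_filter(
                    stack.data[t, c, z].astype(float), footprint=foot, mode="reflect")
    filtered = stack.copy_with(out, normalized=False)
    return invert(normalize_frame(filtered))


def threshold_tissue_state(
    inverted: ImageStack, params: TriageParams | None = None, c: int = 0, z: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(intact, lysed) boolean (t, y, x) masks from the inverted stack.

    intact = pixels strictly above the intact threshold (dye-negative,
    bright after inversion); lysed = strictly below the lysed threshold.
    The strict inequalities make the two masks disjoint by construction.
    """
    params = params or TriageParams()
    if not inverted.normalized:
        raise ValueError("threshold_tissue_state expects a normalized inverted stack")
    frames = inverted.data[:, c, z]
    intact = frames > params.intact_threshold
    lysed = frames < params.lysed_threshold
    return intact, lysed


def detect_lesion_roi(
    intact: np.ndarray,
    lysed: np.ndarray,
    baseline_frames: int,
    close_radius_um: float,
    dx_um: float,
    dilate_radius_um: float = 0.8,
) -> np.ndarray:
    """Frame-by-frame lesion ROI from the tissue-state masks.

    The developing lesion is any area with lysed material or with intact
    (blebbing) material that was not present during the baseline frames.
    A morphological closing bridges the fragmented thresholded pixels into
    a contiguous region, and a small dilation compensates the rim each
    structure loses where its blurred edge crosses back over the
    threshold — an ROI outlines an *area* containing damaged material, so
    it should enclose structures out to their true boundary. An
    expert-drawn ROI, when available, should be used instead — this is
    the automatic fallback.
    """
    if baseline_frames < 1:
        raise ValueError("need at least one baseline frame")
    baseline_union = intact[:baseline_frames].any(axis=0)
    selem = disk(max(1, int(round(close_radius_um / dx_um))))
    grow = disk(int(round(dilate_radius_um / dx_um))) if dilate_radius_um > 0 else None
    out = np.zeros_like(lysed)
    for t in range(lysed.shape[0]):
        raw = lysed[t] | (intact[t] & ~baseline_union)
        if not raw.any():
            out[t] = raw
            continue
        roi = ndimage.binary_closing(raw, structure=selem)
        if grow is not None:
            roi = ndimage.binary_dilation(roi, structure=grow)
        out[t] = roi
    return out


# ---------------------------------------------------------------------------
# Cup detection and content triage


def _binarize_stack(frames: np.ndarray, params: TriageParams) -> np.ndarray:
    """One threshold for the whole time-stack (the convention of stack-level
    binarization in interactive tools): a per-frame threshold would invent
    structure in cup-free baseline frames where only noise is present."""
    if params.binarize == "fixed":
        return frames > params.binarize_threshold
    from skimage.filters import threshold_otsu

    if np.ptp(frames) == 0:
        return np.zeros_like(frames, bool)
    return frames > threshold_otsu(frames)


def detect_phagocytic_cups(
    egfp: ImageStack, params: TriageParams | None = None, c: int = 0, z: int = 0
) -> list[PhagocyticCup]:
    """Fill-holes subtraction cup detector on the EGFP channel.

    Per frame the channel is binarized (Otsu by default), holes are filled
    in 2-D, and the original binary image is subtracted from the filled
    one: what remains is exactly the background enclosed by microglial
    structures — the candidate cup interiors. Candidates are linked over
    (x, y, t) by 26-connected labeling, gated on equivalent diameter
    (median over the cup's frames, within the configured cup-size window)
    and mean circularity (4*pi*A/P^2), and ranked most-circular first.
    """
    params = params or TriageParams()
    frames = egfp.data[:, c, z]
    dx = egfp.geometry.dx
    T = frames.shape[0]
    binary = _binarize_stack(frames, params)
    holes = np.zeros(frames.shape, bool)
    for t in range(T):
        filled = ndimage.binary_fill_holes(binary[t])
        holes[t] = filled & ~binary[t]

    labels, n = ndimage.label(holes, structure=np.ones((3, 3, 3), int))
    cups: list[PhagocyticCup] = []
    lo, hi = params.cup_diameter_range_um
    for obj_id, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        cup = PhagocyticCup(cup_id=-1, frames=[])
        component = labels[sl] == obj_id
        t_off, y_off, x_off = (s.start for s in sl)
        for ti in range(component.shape[0]):
            mask2d = component[ti]
            if not mask2d.any():
                continue
            t = t_off + ti
            area_px = int(mask2d.sum())
            area_um2 = area_px * dx * dx
            eq_diam = 2.0 * np.sqrt(area_um2 / np.pi)
            perim = measure.perimeter(mask2d) * dx
            circ = 4 * np.pi * area_um2 / perim**2 if perim > 0 else 1.0
            rr, cc = np.nonzero(mask2d)
            cup.frames.append(t)
            cup.footprints[t] = (rr + y_off, cc + x_off)
            cup.centroids_um[t] = (float((rr.mean() + y_off) * dx),
                                   float((cc.mean() + x_off) * dx))
            cup.areas_um2[t] = area_um2
            cup.eq_diameters_um[t] = float(eq_diam)
            cup.circularities[t] = float(min(circ, 1.05))
        if not cup.frames:
            continue
        if not (lo <= cup.median_diameter_um <= hi):
            continue
        if cup.mean_circularity < params.min_circularity:
            continue
        cups.append(cup)
    cups.sort(key=lambda cp: cp.mean_circularity, reverse=True)
    for i, cp in enumerate(cups):
        cp.cup_id = i
    return cups


def _eroded_footprint(rr, cc, shape, erosion_px):
    """Interior footprint minus its partial-volume rim; falls back to the
    full footprint when erosion would leave nothing."""
    if erosion_px <= 0 or len(rr) == 0:
        return rr, cc
    y0, y1 = rr.min(), rr.max() + 1
    x0, x1 = cc.min(), cc.max() + 1
    m = np.zeros((y1 - y0, x1 - x0), bool)
    m[rr - y0, cc - x0] = True
    core = ndimage.binary_erosion(m, structure=disk(erosion_px))
    if not core.any():
        return rr, cc
    ry, rx = np.nonzero(core)
    return ry + y0, rx + x0


def classify_cup_contents(
    cups: list[PhagocyticCup],
    intact: np.ndarray,
    lysed: np.ndarray,
    rim_erosion_px: int = 2,
) -> tuple[list[PhagocyticCup], TriageSummary]:
    """Median-content classification of cup interiors.

    Per frame a cup is positive for a state when the median of the binary
    state mask over its interior is non-zero, i.e. strictly more than half
    of the interior pixels carry that state. The interior is eroded by
    ``rim_erosion_px`` first: pixels at the hole boundary are optical
    mixtures of cup wall and content, carry neither state after
    thresholding, and would otherwise dilute the median for small cups.
    Over its lifetime a cup is 'lysed' or 'intact' when positive for only
    that state, 'both' when positive for both (in the same or different
    frames), 'empty' when positive for neither.
    """
    for cup in cups:
        cup.positive_lysed_frames = []
        cup.positive_intact_frames = []
        for t in cup.frames:
            rr, cc = _eroded_footprint(*cup.footprints[t], lysed[t].shape,
                                       rim_erosion_px)
            if len(rr) == 0:
                continue
            if lysed[t][rr, cc].mean() > 0.5:
                cup.positive_lysed_frames.append(t)
            if intact[t][rr, cc].mean() > 0.5:
                cup.positive_intact_frames.append(t)
        pl, pi = bool(cup.positive_lysed_frames), bool(cup.positive_intact_frames)
        cup.content_class = ("both" if pl and pi else "lysed" if pl
                             else "intact" if pi else "empty")
    n = len(cups)
    counts = {k: sum(c.content_class == k for c in cups)
              for k in ("lysed", "intact", "both", "empty")}
    pct = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
    summary = TriageSummary(
        n_cups=n, percent_lysed=pct["lysed"], percent_intact=pct["intact"],
        percent_both=pct["both"], percent_empty=pct["empty"],
    )
    return cups, summary


def enrichment_stats(
    intact: np.ndarray,
    lysed: np.ndarray,
    lesion_roi: np.ndarray,
    cups: list[PhagocyticCup],
    summary: TriageSummary | None = None,
) -> TriageSummary:
    """Lesion-area vs cup-content composition ("In ROI" vs "In PC").

    In ROI: percentage of the lesion-ROI area containing each state,
    averaged over frames with a nonempty ROI. In PC: percentage of cups
    positive for each state, averaged over frames with at least one cup.
    A large In-PC excess over In-ROI indicates selective engulfment.
    """
    if summary is None:
        cups, summary = classify_cup_contents(cups, intact, lysed)
    T = lysed.shape[0]
    roi_l, roi_i = [], []
    for t in range(T):
        roi = lesion_roi[t]
        area = roi.sum()
        if area == 0:
            continue
        roi_l.append(100.0 * (lysed[t] & roi).sum() / area)
        roi_i.append(100.0 * (intact[t] & roi).sum() / area)
    pc_l, pc_i = [], []
    for t in range(T):
        present = [c for c in cups if t in c.frames]
        if not present:
            continue
        pc_l.append(100.0 * sum(t in c.positive_lysed_frames for c in present) / len(present))
        pc_i.append(100.0 * sum(t in c.positive_intact_frames for c in present) / len(present))
    summary.in_roi_lysed = float(np.mean(roi_l)) if roi_l else None
    summary.in_roi_intact = float(np.mean(roi_i)) if roi_i else None
    summary.in_pc_lysed = float(np.mean(pc_l)) if pc_l else None
    summary.in_pc_intact = float(np.mean(pc_i)) if pc_i else None
    return summary


# ---------------------------------------------------------------------------
# Motility


def track_metrics(
    traj: TipTrajectory,
    arrival_radius_um: float = 2.0,
    velocity_frames: tuple[int, int] = (3, 7),
) -> MotilityMetrics:
    """Cumulative path length to arrival and early-approach mean velocity.

    Arrival is the first frame within ``arrival_radius_um`` of the lesion
    point (the last frame when the tip never arrives); the cumulative
    distance sums frame-to-frame displacements up to that frame. The mean
    velocity averages the inter-frame speeds between the 1-based listed
    frames ``velocity_frames`` (default 3-7, i.e. the displacements
    3->4 ... 6->7), the early linear portion of a lesion approach. It is
    undefined for trajectories shorter than 8 frames.
    """
    pos = traj.positions
    n = len(pos)
    steps = np.hypot(*(np.diff(pos, axis=0).T))
    dists = np.hypot(pos[:, 0] - traj.lesion_point_um[0],
                     pos[:, 1] - traj.lesion_point_um[1])
    inside = np.nonzero(dists <= arrival_radius_um)[0]
    arrived = len(inside) > 0
    arr_idx = int(inside[0]) if arrived else n - 1
    cumulative = float(steps[:arr_idx].sum())

    mean_v = None
    if n >= 8:
        dt = np.diff(traj.t_s)
        a, b = velocity_frames  # 1-based listed frames, inclusive
        i0, i1 = a - 1, b - 1   # 0-based indices; speeds for transitions i0..i1-1
        if i1 <= n - 1 and (dt[i0:i1] > 0).all():
            mean_v = float(np.mean(steps[i0:i1] / dt[i0:i1]))
    return MotilityMetrics(
        cumulative_distance_um=cumulative,
        mean_velocity_um_s=mean_v,
        arrival_frame=int(traj.frames[arr_idx]) if arrived else None,
    )


def classify_path(
    traj: TipTrajectory,
    inverted_baseline: np.ndarray,
    dx_um: float,
    params: TriageParams | None = None,
) -> str:
    """'cell_bodies' if the straight baseline->lesion segment crosses a
    cell body, else 'neuropil'.

    Cell bodies are the large dark structures of the baseline shadow
    frame: connected components of (inverted intensity > intact threshold)
    with equivalent diameter of at least ``cell_body_min_diameter_um``.
    The segment is sampled at half-pixel pitch.
    """
    params = params or TriageParams()
    bright = inverted_baseline > params.intact_threshold
    labels, _ = ndimage.label(bright)
    mask = np.zeros_like(bright)
    for prop in measure.regionprops(labels):
        eq_diam = 2.0 * np.sqrt(prop.area * dx_um * dx_um / np.pi)
        if eq_diam >= params.cell_body_min_diameter_um:
            mask[labels == prop.label] = True
    if not mask.any():
        traj.path_class = "neuropil"
        return traj.path_class

    p0 = np.array([traj.y_um[0], traj.x_um[0]])
    p1 = np.array(traj.lesion_point_um)
    length = np.hypot(*(p1 - p0))
    n = max(2, int(np.ceil(length / (dx_um / 2))) + 1)
    pts = p0[None] + np.linspace(0, 1, n)[:, None] * (p1 - p0)[None]
    iy = np.clip(np.round(pts[:, 0] / dx_um).astype(int), 0, mask.shape[0] - 1)
    ix = np.clip(np.round(pts[:, 1] / dx_um).astype(int), 0, mask.shape[1] - 1)
    traj.path_class = "cell_bodies" if mask[iy, ix].any() else "neuropil"
    return traj.path_class


def trajectories_from_table(df, lesion_point_um: tuple[float, float]) -> list[TipTrajectory]:
    """Build TipTrajectory objects from a (tip_id, frame, t_s, y_um, x_um)
    table, e.g. a tracking export or the trajectory phantom output."""
    out = []
    for tip_id, g in df.groupby("tip_id"):
        g = g.sort_values("frame")
        out.append(TipTrajectory(
            frames=g["frame"].to_numpy(), t_s=g["t_s"].to_numpy(),
            y_um=g["y_um"].to_numpy(), x_um=g["x_um"].to_numpy(),
            lesion_point_um=lesion_point_um, tip_id=int(tip_id),
            path_class=str(g["path_class"].iloc[0]) if "path_class" in g else "unassigned",
        ))
    return out
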