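"""Seeded phantom configuration and ground-truth records.

The phantoms emulate the imaging conditions of in-vivo / slice shadow
microscopy — inverted-contrast tissue at a known ECS volume fraction, dark
vessel lumens flanked by bright perivascular stripes, two-channel lesion
time series with ring-shaped phagocytic cups, bead fields, dye-clearance
decays and process-tip trajectories — each with a complete ground-truth
record, so that every analysis stage can be validated against known truth.

Defaults are calibrated to the study conditions this package models:
cortical ECS volume fraction 23%, capillary lumen FWHM 3.7 µm with
perivascular-space FWHM 0.58 µm and a lumen–PVS width correlation of
0.838, 130 phagocytic cups at 63.1/30.8/6.1% lysed/intact/both, process
speeds 0.07 µm/s over 17.1 µm (neuropil paths) and 0.12 µm/s over 28.1 µm
(around cell bodies) at one frame per 20 s, a 47.5% dye-intensity drop
from 1 h to 4 h, and a confocal lateral resolution of 212 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from ..core import RoiMask


class NoiseConfig(BaseModel):
    """Photon shot noise + Gaussian read noise.

    photon_peak: expected photon counts for a pixel at unit intensity
    (Poisson scaling); 0 disables shot noise. read_sigma: sd of additive
    Gaussian read noise, in counts.
    """

    photon_peak: float = Field(default=200.0, ge=0)
    read_sigma: float = Field(default=0.0, ge=0)

    @property
    def enabled(self) -> bool:
        return self.photon_peak > 0 or self.read_sigma > 0


class VesselConfig(BaseModel):
    """Straight-vessel cross-section population.

    Widths are image-domain (apparent, post-blur) FWHMs in µm; the
    per-vessel PVS width follows w = pvs_fwhm_um + coupling_slope *
    (D - lumen_fwhm_um) + eps, eps ~ N(0, coupling_noise_sigma), one draw
    per vessel (both sides symmetric).
    """

    n_vessels: int = Field(default=105, ge=1)
    lumen_fwhm_um: float = Field(default=3.7, gt=0)
    lumen_fwhm_sd_um: float = Field(default=1.0, ge=0)
    pvs_fwhm_um: float = Field(default=0.58, gt=0)
    coupling_slope: float = 0.12
    coupling_noise_sigma: float = Field(default=0.0781, ge=0)
    pvs_offset_um: float = Field(default=0.8, ge=0)  # gap between lumen edge and PVS peak
    baseline: float = Field(default=0.5, gt=0, le=1)
    pvs_amplitude: float = Field(default=0.4, gt=0)

    def population_r(self) -> float:
        """Closed-form Pearson correlation of (D, w) implied by the coupling."""
        b, sd, se = self.coupling_slope, self.lumen_fwhm_sd_um, self.coupling_noise_sigma
        return b * sd / math.sqrt(b * b * sd * sd + se * se)


class LesionConfig(BaseModel):
    """Two-channel laser-lesion time series with phagocytic cups."""

    n_cups: int = Field(default=130, ge=0)
    dx_um: float = Field(default=0.2, gt=0)
    photon_peak: float = Field(default=1000.0, ge=0)
    cup_diameter_um: float = Field(default=6.0, gt=0)
    cup_diameter_sd_um: float = Field(default=0.8, ge=0)
    content_probs: tuple[float, float, float] = (0.631, 0.308, 0.061)  # lysed, intact, both
    exact_counts: bool = False
    n_frames: int = Field(default=8, ge=8)
    dt_s: float = Field(default=20.0, gt=0)

    @model_validator(mode="after")
    def _probs_sum(self):
        if abs(sum(self.content_probs) - 1.0) > 1e-9:
            raise ValueError("content_probs must sum to 1")
        if any(p < 0 for p in self.content_probs):
            raise ValueError("content_probs must be non-negative")
        return self


class TrajectoryClassConfig(BaseModel):
    n_tips: int = Field(ge=1)
    speed_um_s: float = Field(gt=0)
    path_length_um: float = Field(gt=0)


class TrajectoryConfig(BaseModel):
    """Process-tip trajectories toward a lesion point.

    Two path classes: tips traveling through open neuropil, and tips
    detouring around cell bodies (faster but over longer paths).
    """

    neuropil: TrajectoryClassConfig = TrajectoryClassConfig(
        n_tips=29, speed_um_s=0.07, path_length_um=17.1
    )
    cell_bodies: TrajectoryClassConfig = TrajectoryClassConfig(
        n_tips=14, speed_um_s=0.12, path_length_um=28.1
    )
    jitter_sigma_um: float = Field(default=0.1, ge=0)
    dt_s: float = Field(default=20.0, gt=0)
    dwell_frames: int = Field(default=2, ge=0)
    #: radius of the lesion core; tips halt at its boundary, not its centre
    lesion_core_radius_um: float = Field(default=2.0, ge=0)


class ClearanceConfig(BaseModel):
    """Exponential dye-clearance intensity time course.

    Either decay_per_hour (lambda) or target_drop over [drop_t1_h,
    drop_t2_h]; the drop parameterization sets
    lambda = ln(1/(1-d)) / (t2 - t1).
    """

    target_drop: Optional[float] = Field(default=0.475, gt=0, lt=1)
    drop_t1_h: float = 1.0
    drop_t2_h: float = 4.0
    decay_per_hour: Optional[float] = None
    i0: float = Field(default=100.0, gt=0)
    t_start_h: float = 0.0
    t_end_h: float = 5.0
    dt_h: float = Field(default=0.5, gt=0)
    noise_sd: float = Field(default=0.0, ge=0)

    def decay_constant(self) -> float:
        if self.decay_per_hour is not None:
            return self.decay_per_hour
        if self.target_drop is None:
            raise ValueError("clearance needs decay_per_hour or target_drop")
        return math.log(1.0 / (1.0 - self.target_drop)) / (self.drop_t2_h - self.drop_t1_h)


class BeadConfig(BaseModel):
    """Field of isolated sub-diffraction fluorescent beads."""

    n_beads: int = Field(default=50, ge=0)
    fwhm_um: float = Field(default=0.212, gt=0)  # image-domain lateral FWHM
    min_separation_um: float = Field(default=3.0, gt=0)
    amplitude: float = Field(default=1.0, gt=0)
    background: float = Field(default=0.02, ge=0)


class PhantomConfig(BaseModel):
    """Master phantom configuration; ``seed`` fixes every random draw."""

    seed: int = 0
    field_shape: tuple[int, int] = (512, 512)  # (ny, nx) pixels
    dx_um: float = Field(default=0.1, gt=0)
    dz_um: Optional[float] = None
    psf_fwhm_xy_um: float = Field(default=0.32, ge=0)
    psf_fwhm_z_um: Optional[float] = None
    noise: NoiseConfig = NoiseConfig()
    vf_true: float = Field(default=0.23, gt=0, lt=1)
    vessel: VesselConfig = VesselConfig()
    lesion: LesionConfig = LesionConfig()
    trajectories: TrajectoryConfig = TrajectoryConfig()
    clearance: ClearanceConfig = ClearanceConfig()
    beads: BeadConfig = BeadConfig()

    def rng(self, stream: str = "") -> np.random.Generator:
        """Named deterministic substream so generators do not share draws."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, _stream_key(stream)])
        )


def _stream_key(name: str) -> int:
    return sum((i + 1) * b for i, b in enumerate(name.encode())) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class VesselRecord:
    label: str
    frame: int
    lumen_fwhm_um: float
    pvs_fwhm_um: float          # one draw per vessel, both sides
    center_row_um: float
    axis_points_um: list        # [(y, x), ...] polyline along the centerline


@dataclass
class CupRecord:
    cup_id: int
    content_class: str          # lysed | intact | both
    centroid_um: tuple[float, float]
    interior_diameter_um: float
    frame_start: int
    frame_end: int


@dataclass
class TrajectoryRecord:
    tip_id: int
    path_class: str             # neuropil | cell_bodies
    speed_um_s: float
    path_length_um: float
    lesion_point_um: tuple[float, float]


@dataclass
class BeadRecord:
    bead_id: int
    y_um: float
    x_um: float
    fwhm_um: float


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    ecs_mask: Optional[RoiMask] = None
    cell_body_mask: Optional[RoiMask] = None
    pure_ecs_rect: Optional[tuple[int, int, int, int]] = None  # (y0, y1, x0, x1) px
    achieved_vf: Optional[float] = None
    vessel_records: list = field(default_factory=list)
    cup_records: list = field(default_factory=list)
    lesion_masks: Optional[np.ndarray] = None  # (t, y, x) bool
    trajectory_records: list = field(default_factory=list)
    bead_records: list = field(default_factory=list)
    clearance_params: Optional[dict] = None
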