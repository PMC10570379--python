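"""Perivascular-space and vessel-lumen width measurement.

A shadow-image cross-section of a vessel shows a dark lumen trough flanked
by two bright perivascular-space (PVS) peaks. Because the flanks and the
trough overlap at capillary scale, the three features are fitted
simultaneously:

    I(x) = baseline + A_L G(x; mu_L, s_L) + A_R G(x; mu_R, s_R)
                    - A_0 G(x; mu_0, s_0)

with A_L, A_R, A_0 >= 0 and mu_L < mu_0 < mu_R. The lumen diameter is the
FWHM of the trough and the PVS widths the FWHMs of the flank peaks. A
flank whose fitted amplitude does not exceed 3x the residual sd is
reported missing (fitting noise as anatomy is worse than a missing value),
and a profile with no significant trough is flagged ``no_vessel``.

The lumen-diameter vs PVS-width association across vessels is summarized
by a Pearson correlation; by default the two sides of each vessel are
averaged into one PVS width per vessel (selectable to per-side pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import ImageStack
from .profiles import FWHM_PER_SIGMA, LineProfile, extract_line_profile

__all__ = [
    "VesselAxis",
    "VesselMeasurement",
    "CorrelationResult",
    "place_orthogonal_profiles",
    "measure_vessel_cross_section",
    "pvs_vessel_correlation",
]


@dataclass
class VesselAxis:
    """Polyline (y, x) points in µm tracing a vessel centreline."""

    points_um: np.ndarray
    label: str = "vessel"

    def __post_init__(self):
        self.points_um = np.asarray(self.points_um, float).reshape(-1, 2)
        if len(self.points_um) < 2:
            raise ValueError("vessel axis needs at least 2 points")
        seg = np.diff(self.points_um, axis=0)
        if (np.hypot(seg[:, 0], seg[:, 1]) <= 0).any():
            raise ValueError("vessel axis has zero-length segments")

    def arclength(self) -> np.ndarray:
        seg = np.diff(self.points_um, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    def point_and_tangent(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Position and unit tangent at arclength ``s`` (µm)."""
        cum = self.arclength()
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right")) - 1
        i = min(i, len(cum) - 2)
        seg = self.points_um[i + 1] - self.points_um[i]
        length = float(np.hypot(*seg))
        frac = (s - cum[i]) / length
        return self.points_um[i] + frac * seg, seg / length


@dataclass
class VesselMeasurement:
    vessel_label: str
    station_um: float
    lumen_fwhm_um: float | None
    pvs_fwhm_left_um: float | None
    pvs_fwhm_right_um: float | None
    rmse: float
    quality: str  # "ok" | "no_vessel" | "fit_failed"

    @property
    def pvs_mean_um(self) -> float | None:
        sides = [w for w in (self.pvs_fwhm_left_um, self.pvs_fwhm_right_um)
                 if w is not None]
        return float(np.mean(sides)) if sides else None


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def place_orthogonal_profiles(
    stack: ImageStack,
    axis: VesselAxis,
    spacing_um: float,
    half_length_um: float,
    averaging_width: int = 5,
    t: int = 0,
    c: int = 0,
    z: int = 0,
) -> list[tuple[float, LineProfile]]:
    """Profiles perpendicular to the axis every ``spacing_um`` along it.

    Returns (station arclength, profile) pairs; stations whose profile
    would leave the image are skipped. Left/right along each profile is
    defined by the sign of the perpendicular offset relative to the local
    tangent direction (the profile runs from -half_length to +half_length).
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    plane = stack.plane(t, c, z)
    dx = stack.geometry.dx
    total = axis.arclength()[-1]
    out = []
    s = 0.0
    while s <= total + 1e-9:
        point, tangent = axis.point_and_tangent(min(s, total))
        normal = np.array([-tangent[1], tangent[0]])
        p0 = point - half_length_um * normal
        p1 = point + half_length_um * normal
        try:
            prof = extract_line_profile(plane, tuple(p0), tuple(p1), dx, averaging_width)
        except ValueError:
            s += spacing_um
            continue
        out.append((s, prof))
        s += spacing_um
    return out


def _composite(x, base, al, mul, sl, ar, mur, sr, a0, mu0, s0):
    return (base
            + al * np.exp(-0.5 * ((x - mul) / sl) ** 2)
            + ar * np.exp(-0.5 * ((x - mur) / sr) ** 2)
            - a0 * np.exp(-0.5 * ((x - mu0) / s0) ** 2))


def measure_vessel_cross_section(
    profile: LineProfile,
    vessel_label: str = "vessel",
    station_um: float = 0.0,
    significance_factor: float = 3.0,
) -> VesselMeasurement:
    """Fit the two-peak/one-trough model to one cross-section profile."""
    x, y = profile.positions, profile.values
    if len(x) < 10:
        raise ValueError("profile too short for a composite fit")
    span = x[-1] - x[0]
    pitch = x[1] - x[0]

    # moment-free initialization from the profile's extrema
    i0 = int(np.argmin(y))
    mu0 = x[i0]
    base0 = float(np.median(y))
    depth = base0 - y[i0]
    if depth <= 0 or np.ptp(y) == 0:
        return VesselMeasurement(vessel_label, station_um, None, None, None,
                                 float(np.std(y)), "no_vessel")
    # trough width guess from half-depth crossings
    below = y < base0 - depth / 2
    s0_init = max(pitch, np.count_nonzero(below) * pitch / FWHM_PER_SIGMA)
    left, right = y[:i0], y[i0 + 1:]
    il = int(np.argmax(left)) if len(left) else 0
    ir = i0 + 1 + int(np.argmax(right)) if len(right) else len(y) - 1
    p0 = [base0,
          max(y[il] - base0, 0.05 * depth), x[il], 0.3,
          max(y[ir] - base0, 0.05 * depth), x[ir], 0.3,
          depth, mu0, s0_init]
    lb = [-np.inf, 0, x[0], pitch / 4, 0, x[0], pitch / 4, 0, x[0], pitch / 4]
    ub = [np.inf, np.inf, x[-1], span, np.inf, x[-1], span, np.inf, x[-1], span]
    try:
        popt, _ = optimize.curve_fit(_composite, x, y, p0=p0, bounds=(lb, ub),
                                     maxfev=20000)
    except (RuntimeError, ValueError):
        return VesselMeasurement(vessel_label, station_um, None, None, None,
                                 float(np.std(y)), "fit_failed")
    base, al, mul, sl, ar, mur, sr, a0, mu0, s0 = popt
    resid_sd = float(np.std(y - _composite(x, *popt)))
    if a0 < significance_factor * resid_sd:
        return VesselMeasurement(vessel_label, station_um, None, None, None,
                                 resid_sd, "no_vessel")
    if not (mul < mu0 < mur):
        return VesselMeasurement(vessel_label, station_um, None, None, None,
                                 resid_sd, "fit_failed")
    # flanks must clear the noise floor AND be non-negligible against the
    # trough depth (the latter guards the noiseless limit, where resid -> 0)
    amp_floor = max(significance_factor * resid_sd, 0.05 * a0)
    wl = FWHM_PER_SIGMA * sl if al >= amp_floor else None
    wr = FWHM_PER_SIGMA * sr if ar >= amp_floor else None
    return VesselMeasurement(
        vessel_label, station_um,
        lumen_fwhm_um=float(FWHM_PER_SIGMA * s0),
        pvs_fwhm_left_um=None if wl is None else float(wl),
        pvs_fwhm_right_um=None if wr is None else float(wr),
        rmse=resid_sd, quality="ok",
    )


def pvs_vessel_correlation(
    measurements: list[VesselMeasurement],
    pairing: str = "mean",
) -> CorrelationResult:
    """Pearson correlation between lumen diameter and PVS width.

    pairing 'mean' (default): one pair per measurement, PVS width = mean
    of the available sides. pairing 'sides': each measured side is its own
    pair. Only 'ok'-quality measurements with at least one PVS side enter.
    """
    pairs: list[tuple[float, float]] = []
    for m in measurements:
        if m.quality != "ok" or m.lumen_fwhm_um is None:
            continue
        if pairing == "mean":
            w = m.pvs_mean_um
            if w is not None:
                pairs.append((m.lumen_fwhm_um, w))
        elif pairing == "sides":
            for w in (m.pvs_fwhm_left_um, m.pvs_fwhm_right_um):
                if w is not None:
                    pairs.append((m.lumen_fwhm_um, w))
        else:
            raise ValueError(f"unknown pairing {pairing!r}")
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 (lumen, PVS) pairs, got {len(pairs)}")
    d, w = np.array(pairs).T
    r, p = stats.pearsonr(d, w)
    return CorrelationResult(r=float(r), p=float(p), n=len(pairs))
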