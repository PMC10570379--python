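"""Core data model and raster primitives for shadow-image analysis.

Shadow imaging labels the extracellular fluid, so cells appear as dark
silhouettes against a bright background. Every pipeline in this package
operates on :class:`ImageStack`, a five-axis raster with fixed axis order
``(t, c, z, y, x)`` and explicit physical pixel geometry; singleton axes
are always materialized so downstream code never guesses dimensionality.

Coordinates are 0-based and pixel-centered: the physical position of index
``i`` along an axis with pitch ``d`` is ``i * d`` micrometres. Sub-pixel
values are obtained by bilinear interpolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "PixelGeometry",
    "ImageStack",
    "RoiMask",
    "MeasurementTable",
    "read_stack",
    "write_stack",
    "normalize_frame",
    "invert",
]

AXES = "tczyx"


@dataclass(frozen=True)
class PixelGeometry:
    """Physical sampling geometry of a stack.

    Parameters
    ----------
    dx, dy : float
        Pixel pitch in micrometres along x and y. Must be equal unless
        ``allow_anisotropic_xy`` is set (square pixels are the norm for
        the point-scanning and camera systems this package models).
    dz : float, optional
        Plane spacing in micrometres for z-stacks.
    dt : float, optional
        Frame interval in seconds for time series.
    """

    dx: float
    dy: float | None = None
    dz: float | None = None
    dt: float | None = None
    allow_anisotropic_xy: bool = False

    def __post_init__(self):
        if self.dy is None:
            object.__setattr__(self, "dy", self.dx)
        for name in ("dx", "dy", "dz", "dt"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not self.allow_anisotropic_xy and not np.isclose(self.dx, self.dy):
            raise ValueError(
                f"dx ({self.dx}) != dy ({self.dy}); square pixels expected "
                "(pass allow_anisotropic_xy=True to override)"
            )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("dx", "dy", "dz", "dt")}


@dataclass
class ImageStack:
    """Five-axis intensity raster ``(t, c, z, y, x)`` with geometry.

    Intensities are non-negative, arbitrary units. ``normalized`` marks a
    stack whose values lie in [0, 1] (produced by :func:`normalize_frame`).
    ``saturated`` flags pixels that sat at the container's maximum
    representable value on read; quantitative reference measurements must
    refuse regions containing such pixels (detectors must stay in their
    linear range for intensity-based volume-fraction estimation).
    """

    data: np.ndarray
    geometry: PixelGeometry
    normalized: bool = False
    saturated: np.ndarray | None = None
    degenerate_frames: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.data = coerce_tczyx(self.data)
        if self.data.min() < 0:
            raise ValueError("ImageStack intensities must be non-negative")
        if self.normalized and self.data.size and self.data.max() > 1 + 1e-9:
            raise ValueError("normalized stack has values > 1")
        if self.saturated is not None:
            self.saturated = coerce_tczyx(np.asarray(self.saturated, bool))
            if self.saturated.shape != self.data.shape:
                raise ValueError("saturation mask shape mismatch")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def plane(self, t: int = 0, c: int = 0, z: int = 0) -> np.ndarray:
        """Return one (y, x) plane as a 2-D view."""
        return self.data[t, c, z]

    def copy_with(self, data: np.ndarray, **kw) -> "ImageStack":
        opts = dict(
            geometry=self.geometry,
            normalized=self.normalized,
            saturated=self.saturated,
            degenerate_frames=list(self.degenerate_frames),
        )
        opts.update(kw)
        return ImageStack(data, **opts)


def coerce_tczyx(a: np.ndarray) -> np.ndarray:
    """Left-pad singleton axes so that ``a`` becomes 5-D (t, c, z, y, x)."""
    a = np.asarray(a)
    if a.ndim > 5:
        raise ValueError(f"array has {a.ndim} axes; at most 5 (t,c,z,y,x) supported")
    if a.ndim < 2:
        raise ValueError("an image needs at least (y, x) axes")
    while a.ndim < 5:
        a = a[np.newaxis]
    return a


@dataclass
class RoiMask:
    """Boolean region of interest aligned to the (y, x) or (z, y, x) axes."""

    mask: np.ndarray
    label: str = "roi"
    allow_empty: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError("RoiMask must be 2-D (y,x) or 3-D (z,y,x)")
        if not self.allow_empty and not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class MeasurementTable:
    """A pandas DataFrame plus provenance (operation id and parameters)."""

    frame: "object"  # pandas.DataFrame; untyped to keep pandas import lazy
    operation: str
    params: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = {"operation": self.operation, "params": _jsonable(self.params)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as an ImageJ-hyperstack TIFF with geometry metadata."""
    g = stack.geometry
    # ImageJ hyperstacks require TZCYX page order
    data = np.transpose(stack.data, (0, 2, 1, 3, 4))
    meta = {"axes": "TZCYX", "unit": "um"}
    if g.dz is not None:
        meta["spacing"] = g.dz
    if g.dt is not None:
        meta["finterval"] = g.dt
    tifffile.imwrite(
        str(path),
        data,
        imagej=data.dtype in (np.dtype("uint8"), np.dtype("uint16"), np.dtype("float32")),
        resolution=(1.0 / g.dx, 1.0 / g.dy),
        metadata=meta,
    )


def read_stack(
    path: str | Path, geometry_override: PixelGeometry | None = None
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Axis metadata (ImageJ hyperstack tags) is honored when present;
    otherwise pages are interpreted as leading axes of (t, c, z, y, x).
    Pixel geometry comes from the TIFF resolution tags, or from
    ``geometry_override``; an error is raised if neither is available.
    Integer rasters at their dtype's maximum are flagged saturated.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. 'YX', 'TYX', 'TCZYX', 'QYX'
        geometry = _geometry_from_tiff(tf, geometry_override)

    data = _reorder_axes(data, axes)
    saturated = None
    if np.issubdtype(data.dtype, np.integer):
        cap = np.iinfo(data.dtype).max
        if (data == cap).any():
            saturated = data == cap
    return ImageStack(
        data.astype(np.float64) if not np.issubdtype(data.dtype, np.floating) else data,
        geometry=geometry,
        saturated=saturated,
    )


def _reorder_axes(data: np.ndarray, axes: str) -> np.ndarray:
    axes = axes.upper().replace("S", "C").replace("Q", "T").replace("I", "T")
    if len(axes) != data.ndim:
        raise ValueError(f"axis string {axes!r} does not match array of {data.ndim} axes")
    unknown = set(axes) - set("TCZYX")
    if unknown:
        raise ValueError(f"cannot interpret TIFF axes {sorted(unknown)}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"ambiguous TIFF axes {axes!r}")
    # insert missing axes then transpose into TCZYX
    for ax in "TCZYX":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "TCZYX"]
    return np.transpose(data, order)


def _geometry_from_tiff(tf, override: PixelGeometry | None) -> PixelGeometry:
    page = tf.pages[0]
    ij = tf.imagej_metadata or {}
    dx = dy = None
    # ResolutionUnit == 1 means "no absolute unit": only meaningful when the
    # ImageJ metadata names a unit (the hyperstack convention)
    unit_tag = page.tags.get("ResolutionUnit")
    has_unit = (unit_tag is not None and int(unit_tag.value) != 1) or "unit" in ij
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        if has_unit and xres[0] and yres[0]:
            dx = xres[1] / xres[0]
            dy = yres[1] / yres[0]
    except (KeyError, TypeError, ZeroDivisionError):
        pass
    dz = dt = None
    dz = ij.get("spacing")
    dt = ij.get("finterval")
    if dx is None or dx <= 0:
        if override is None:
            raise ValueError(f"missing geometry: {tf.filename} has no resolution tags and no override given")
        return override
    if override is not None:
        return override
    return PixelGeometry(dx=dx, dy=dy, dz=dz, dt=dt, allow_anisotropic_xy=not np.isclose(dx, dy))


# ---------------------------------------------------------------------------
# Elementary transforms


def normalize_frame(stack: ImageStack, lo_pct: float = 0.1, hi_pct: float = 99.9) -> ImageStack:
    """Robust per-frame contrast normalization into [0, 1].

    Each (t, c, z) frame is mapped affinely so its ``lo_pct`` percentile
    goes to 0 and its ``hi_pct`` percentile to 1, then clipped. Robust
    percentiles (rather than min/max) make downstream fixed fractional
    thresholds insensitive to isolated hot or dead pixels. A frame whose
    two percentiles coincide carries no contrast; it is set to zero and
    recorded in ``degenerate_frames``.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    out = np.empty_like(stack.data, dtype=np.float64)
    degenerate: list[tuple[int, int, int]] = []
    T, C, Z = stack.shape[:3]
    for t in range(T):
        for c in range(C):
            for z in range(Z):
                frame = stack.data[t, c, z]
                lo, hi = np.percentile(frame, [lo_pct, hi_pct])
                if hi <= lo:
                    out[t, c, z] = 0.0
                    degenerate.append((t, c, z))
                else:
                    out[t, c, z] = np.clip((frame - lo) / (hi - lo), 0.0, 1.0)
    return stack.copy_with(out, normalized=True, degenerate_frames=degenerate)


def invert(stack: ImageStack) -> ImageStack:
    """Invert a normalized stack: v -> 1 - v.

    Turns a shadow image (bright extracellular space, dark cells) into a
    conventional-contrast image where cellular structures are bright. An
    involution: ``invert(invert(s))`` equals ``s``.
    """
    if not stack.normalized:
        raise ValueError("invert requires a normalized stack (values in [0,1])")
    return stack.copy_with(1.0 - stack.data)
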