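"""Cheek region-of-interest geometry.

The cheeks sit over the facial artery and show the strongest
pulse-driven color change, so two small square ROIs are cut from the
face box: their x offsets at 30% and 70% of the face width, the y
offset at 50% of the face height, and both width and height at 8% of
the face *width* (the size deliberately tracks W, not H, so the ROI
stays square).  Fractions are configurable, and more than two regions
(forehead, chin, ...) may be supplied for multi-ROI fusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ConfigurationError, DegenerateGeometryError
from .tracking import FaceBox, round_half_away


@dataclass(frozen=True)
class RoiSpec:
    """Fractional placement of cheek ROIs within a face box."""

    x_frac_1: float = 0.3
    x_frac_2: float = 0.7
    y_frac: float = 0.5
    size_frac: float = 0.08

    def __post_init__(self):
        for name in ("x_frac_1", "x_frac_2", "y_frac", "size_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"RoiSpec.{name} must be in (0, 1), got {v}")

    @property
    def x_fracs(self) -> tuple[float, ...]:
        return (self.x_frac_1, self.x_frac_2)


@dataclass(frozen=True)
class RoiBox:
    """Half-open pixel rectangle [x, x+w) x [y, y+h)."""

    roi_id: str
    x: int
    y: int
    w: int
    h: int

    @property
    def area(self) -> int:
        return self.w * self.h


def cheek_rois(
    face: FaceBox,
    spec: RoiSpec = RoiSpec(),
    frame_w: int | None = None,
    frame_h: int | None = None,
) -> list[RoiBox]:
    """Place the cheek ROIs inside a (smoothed) face box.

    ROI1 sits at (X + x_frac_1*W, Y + y_frac*H), ROI2 at
    (X + x_frac_2*W, Y + y_frac*H); both are size_frac*W square.
    Coordinates are rounded to the nearest integer (ties away from
    zero) and, when frame dimensions are given, clamped to the frame
    with a warning.  An ROI that rounds to zero area raises
    :class:`DegenerateGeometryError`.
    """
    size = round_half_away(spec.size_frac * face.w)
    if size < 1:
        raise DegenerateGeometryError(
            f"ROI size {spec.size_frac:.3f} x W={face.w} rounds to zero pixels"
        )
    y = round_half_away(face.y + spec.y_frac * face.h)
    rois = []
    for i, xf in enumerate(spec.x_fracs, start=1):
        x = round_half_away(face.x + xf * face.w)
        roi = RoiBox(f"ROI{i}", x, y, size, size)
        if frame_w is not None and frame_h is not None:
            roi = _clamp(roi, frame_w, frame_h)
        rois.append(roi)
    return rois


def _clamp(roi: RoiBox, frame_w: int, frame_h: int) -> RoiBox:
    x = min(max(roi.x, 0), frame_w - 1)
    y = min(max(roi.y, 0), frame_h - 1)
    w = min(roi.w, frame_w - x)
    h = min(roi.h, frame_h - y)
    if w < 1 or h < 1:
        raise DegenerateGeometryError(
            f"{roi.roi_id} clamped to zero area inside {frame_w}x{frame_h} frame"
        )
    if (x, y, w, h) != (roi.x, roi.y, roi.w, roi.h):
        warnings.warn(
            f"{roi.roi_id} clamped to frame bounds: "
            f"({roi.x},{roi.y},{roi.w},{roi.h}) -> ({x},{y},{w},{h})",
            stacklevel=3,
        )
    return RoiBox(roi.roi_id, x, y, w, h)
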