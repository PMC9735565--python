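"""Cg chrominance extraction and dropout repair.

The skin's blood-volume pulse modulates the green channel more strongly
than red and blue, and common-mode illumination changes hit all three
channels alike.  The Cg component of the YCgCo color space,

    Cg = -0.25 R + 0.5 G - 0.25 B,

therefore amplifies the pulsatile part while cancelling common-mode
drift, which is why the per-ROI mean RGB triple is reduced to a single
Cg value per frame.  Frames with no face detection leave holes in the
series; those are repaired by natural cubic-spline interpolation
(second derivative zero at both ends) as long as no single gap exceeds
a configurable duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import DegenerateGeometryError, UnrecoverableGapError

#: Cg weights applied to (R, G, B) channel means.
CG_WEIGHTS = (-0.25, 0.5, -0.25)

#: Default longest repairable dropout gap, seconds.  Beyond about two
#: seconds more than a full cardiac cycle is missing at any plausible
#: rate and a spline cannot reconstruct it.
DEFAULT_MAX_GAP_S = 2.0

_CSV_COLUMNS = ["frame", "t_sec", "roi_id", "mean_r", "mean_g", "mean_b", "cg", "valid"]


def roi_mean_rgb(frame: np.ndarray, roi) -> tuple[float, float, float]:
    """Mean R, G, B over the half-open rectangle [x, x+w) x [y, y+h).

    `frame` is an (H, W, 3) array in semantic R, G, B channel order;
    values are returned in native [0, 255] units.
    """
    x, y, w, h = roi.x, roi.y, roi.w, roi.h
    if w < 1 or h < 1:
        raise DegenerateGeometryError(f"ROI {getattr(roi, 'roi_id', '?')} has zero area")
    patch = np.asarray(frame, dtype=np.float64)[y : y + h, x : x + w, :]
    if patch.size == 0:
        raise DegenerateGeometryError(
            f"ROI {getattr(roi, 'roi_id', '?')} lies outside the frame"
        )
    means = patch.reshape(-1, 3).mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def to_cg(mean_r, mean_g, mean_b):
    """Cg chrominance of an RGB triple (scalar or array-valued)."""
    wr, wg, wb = CG_WEIGHTS
    return wr * np.asarray(mean_r) + wg * np.asarray(mean_g) + wb * np.asarray(mean_b)


@dataclass
class ChromaSeries:
    """Uniformly sampled per-frame chroma record for one ROI.

    Invalid samples (dropout frames) carry NaN channel values and
    ``valid=False``; timestamps are ``frame_index / fs`` throughout.
    """

    roi_id: str
    fs: float
    frame_index: np.ndarray
    mean_r: np.ndarray
    mean_g: np.ndarray
    mean_b: np.ndarray
    cg: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        for name in ("mean_r", "mean_g", "mean_b", "cg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.frame_index)
        for name in ("mean_r", "mean_g", "mean_b", "cg", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")

    @property
    def t_sec(self) -> np.ndarray:
        return self.frame_index / self.fs

    @property
    def n(self) -> int:
        return len(self.frame_index)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @classmethod
    def from_rgb(cls, roi_id, fs, frame_index, mean_r, mean_g, mean_b, valid=None):
        mean_r = np.asarray(mean_r, dtype=np.float64)
        if valid is None:
            valid = np.ones(len(mean_r), dtype=bool)
        cg = to_cg(mean_r, mean_g, mean_b)
        return cls(roi_id, fs, frame_index, mean_r, mean_g, mean_b, cg, valid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "t_sec": self.t_sec,
                "roi_id": self.roi_id,
                "mean_r": self.mean_r,
                "mean_g": self.mean_g,
                "mean_b": self.mean_b,
                "cg": self.cg,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, roi_id: str | None = None) -> "ChromaSeries":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"chroma CSV missing columns: {missing}")
        if roi_id is not None:
            df = df[df["roi_id"] == roi_id]
        ids = df["roi_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"chroma CSV holds {len(ids)} ROI ids; pass roi_id=")
        df = df.sort_values("frame")
        fi = df["frame"].to_numpy()
        dt = np.diff(df["t_sec"].to_numpy())
        fs = 1.0 / np.median(dt) if len(dt) else 30.0
        return cls(
            str(ids[0]),
            float(fs),
            fi,
            df["mean_r"].to_numpy(),
            df["mean_g"].to_numpy(),
            df["mean_b"].to_numpy(),
            df["cg"].to_numpy(),
            df["valid"].to_numpy().astype(bool),
        )


def _invalid_runs(valid: np.ndarray):
    """Yield (start, stop) index pairs of maximal invalid runs (half-open)."""
    idx = np.flatnonzero(~valid)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    yield from zip(starts, stops)


def interpolate_gaps(
    series: ChromaSeries, max_gap_s: float = DEFAULT_MAX_GAP_S
) -> ChromaSeries:
    """Repair invalid interior samples by natural cubic splines.

    Leading/trailing invalid runs are trimmed rather than extrapolated.
    Each channel (and Cg itself) is splined through its valid (t, value)
    points with zero second derivative at both ends.  A single gap
    longer than `max_gap_s` raises :class:`UnrecoverableGapError`
    naming the gap's time span.
    """
    valid = series.valid
    if valid.sum() < 4:
        raise UnrecoverableGapError(
            f"only {int(valid.sum())} valid samples; need at least 4 to spline"
        )
    first, last = np.flatnonzero(valid)[[0, -1]]
    sl = slice(first, last + 1)
    valid = valid[sl]
    t = series.t_sec[sl]

    for start, stop in _invalid_runs(valid):
        gap_s = (stop - start) / series.fs
        if gap_s > max_gap_s:
            t0, t1 = t[start], t[stop - 1] + 1.0 / series.fs
            raise UnrecoverableGapError(
                f"dropout gap of {gap_s:.2f} s at t=[{t0:.2f}, {t1:.2f}] s "
                f"exceeds max_gap_s={max_gap_s}",
                start_s=float(t0),
                end_s=float(t1),
            )

    out = {}
    tv = t[valid]
    for name in ("mean_r", "mean_g", "mean_b", "cg"):
        vals = getattr(series, name)[sl].copy()
        if not valid.all():
            spline = CubicSpline(tv, vals[valid], bc_type="natural")
            vals[~valid] = spline(t[~valid])
        out[name] = vals

    return ChromaSeries(
        roi_id=series.roi_id,
        fs=series.fs,
        frame_index=series.frame_index[sl],
        valid=np.ones(len(t), dtype=bool),
        **out,
    )
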