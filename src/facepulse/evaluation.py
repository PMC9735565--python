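"""Multi-ROI fusion and accuracy metrics.

Illumination rarely hits both cheeks equally, so per-ROI rate
estimates are combined by a weighted average (default weights 0.5 /
0.5 for two cheeks, uniform for more regions).  Estimates are scored
against a reference rate with MAE, RMSE, MAPE and the Pearson
correlation coefficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass
class PulseEstimate:
    """One pulse-rate value with method and ROI provenance."""

    bpm: float
    method: str = ""
    roi_id: str = ""
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not np.isfinite(self.bpm):
            raise ConfigurationError(f"non-finite bpm {self.bpm}")
        if self.window[1] < self.window[0]:
            raise ConfigurationError(f"ill-ordered window {self.window}")


@dataclass
class EvalReport:
    """Error metrics for a batch of estimate/reference pairs."""

    n: int
    mae: float
    rmse: float
    mape: float
    r: float

    def to_dict(self) -> dict:
        return {"n": self.n, "mae": self.mae, "rmse": self.rmse, "mape": self.mape, "r": self.r}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def fuse_weighted(
    estimates: list[PulseEstimate], weights: list[float] | None = None
) -> PulseEstimate:
    """Weighted average of per-ROI estimates (weights normalized to 1).

    ``None`` weights mean uniform.  All-zero or negative weights are a
    configuration error.
    """
    if not estimates:
        raise ConfigurationError("no estimates to fuse")
    if weights is None:
        weights = [1.0] * len(estimates)
    if len(weights) != len(estimates):
        raise ConfigurationError(
            f"{len(estimates)} estimates but {len(weights)} weights"
        )
    w = np.asarray(weights, dtype=np.float64)
    if (w < 0).any():
        raise ConfigurationError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ConfigurationError("weights sum to zero")
    w = w / total
    bpm = float(np.dot(w, [e.bpm for e in estimates]))
    windows = [e.window for e in estimates]
    window = (min(s for s, _ in windows), max(e for _, e in windows))
    method = estimates[0].method if len({e.method for e in estimates}) == 1 else "mixed"
    return PulseEstimate(bpm=bpm, method=method, roi_id="fused", window=window)


def score(predicted, reference) -> EvalReport:
    """MAE, RMSE, MAPE (%) and Pearson r of predicted vs reference bpm.

    MAPE requires strictly positive reference values; a constant
    vector makes r undefined, reported as NaN with a warning.
    """
    yhat = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(reference, dtype=np.float64)
    if yhat.shape != y.shape or y.ndim != 1 or len(y) == 0:
        raise ConfigurationError(
            f"predicted {yhat.shape} and reference {y.shape} must be equal-length 1-D"
        )
    if (y <= 0).any():
        raise ConfigurationError("reference rates must be > 0 for MAPE")
    err = y - yhat
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    mape = float(100.0 * np.abs(err / y).mean())
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        warnings.warn("constant vector: Pearson r undefined, reporting NaN", stacklevel=2)
        r = float("nan")
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
    return EvalReport(n=len(y), mae=mae, rmse=rmse, mape=mape, r=r)


def read_reference(path) -> pd.DataFrame:
    """Read a reference trace CSV with columns (t_sec, bpm) or (t_sec, ppg).

    Raw PPG traces are reduced to a rate with the same band-isolation
    and RR-interval machinery the facial estimator uses, giving a
    single whole-record bpm attached to the full time span.
    """
    df = pd.read_csv(path)
    if "t_sec" not in df.columns:
        raise ConfigurationError(f"{path}: reference CSV needs a t_sec column")
    if "bpm" in df.columns:
        return df[["t_sec", "bpm"]]
    if "ppg" not in df.columns:
        raise ConfigurationError(f"{path}: reference CSV needs a bpm or ppg column")
    from .chroma import ChromaSeries
    from .pulse import estimate_rfpr

    t = df["t_sec"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    base = 100.0
    series = ChromaSeries.from_rgb(
        "ppg", fs, np.arange(len(t)), np.full(len(t), base),
        base + 2.0 * df["ppg"].to_numpy(), np.full(len(t), base),
    )
    est = estimate_rfpr(series)
    return pd.DataFrame({"t_sec": [t[0], t[-1]], "bpm": [est.bpm, est.bpm]})


def reference_bpm_for_window(ref: pd.DataFrame, window: tuple[float, float]) -> float:
    """Mean reference bpm over an estimate's time window.

    Reference samples rarely align with estimate windows; the bpm
    samples falling inside the window are averaged (nearest sample is
    used when none falls inside).
    """
    t = ref["t_sec"].to_numpy()
    bpm = ref["bpm"].to_numpy()
    inside = (t >= window[0]) & (t <= window[1])
    if inside.any():
        return float(bpm[inside].mean())
    mid = 0.5 * (window[0] + window[1])
    return float(bpm[np.argmin(np.abs(t - mid))])
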