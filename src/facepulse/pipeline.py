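"""End-to-end orchestration: frames -> chroma -> pulse-rate estimates.

The stage order mirrors the measurement chain: detect a face per
frame, stabilize the box with the moving-average filter, cut cheek
ROIs, average RGB and convert to Cg, spline over detection dropouts,
band-isolate, estimate a rate per ROI with the chosen method, and
fuse the per-ROI rates by weighted average.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .baselines import AcfConfig, StftConfig, acf_rate, ica_bpf_rate, peak_count_rate, stft_rate
from .chroma import DEFAULT_MAX_GAP_S, ChromaSeries, interpolate_gaps, roi_mean_rgb
from .errors import ConfigurationError, NoFaceDetectedError
from .evaluation import PulseEstimate, fuse_weighted
from .pulse import BandConfig, band_isolate, detect_peaks, rfpr
from .roi import RoiSpec, cheek_rois
from .tracking import DEFAULT_MAF_WINDOW, FaceBox, MovingAverageSmoother, detect_face

log = logging.getLogger(__name__)

METHODS = ("rfpr", "stft", "acf", "ica-bpf", "peak-count")


@dataclass
class PipelineConfig:
    """Resolved knobs for one run; defaults match the method's study setup."""

    method: str = "rfpr"
    fps: float = 30.0
    band: BandConfig = field(default_factory=BandConfig)
    maf_n: int = DEFAULT_MAF_WINDOW
    smooth_size: bool = True
    roi_spec: RoiSpec = field(default_factory=RoiSpec)
    weights: tuple[float, ...] | None = None
    max_gap_s: float = DEFAULT_MAX_GAP_S
    prominence_frac: float = 0.3
    stft: StftConfig = field(default_factory=StftConfig)
    acf: AcfConfig = field(default_factory=AcfConfig)
    ica_seed: int = 0
    ica_component: int | None = None
    peak_window_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")
        if self.maf_n < 1:
            raise ConfigurationError("maf_n must be >= 1")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["band"] = {"f_min": self.band.f_min, "f_max": self.band.f_max}
        d["roi_spec"] = asdict(self.roi_spec)
        d["stft"] = asdict(self.stft)
        d["acf"] = asdict(self.acf)
        if self.weights is not None:
            d["weights"] = list(self.weights)
        return d


def extract_chroma(frames, detector, cfg: PipelineConfig) -> dict[str, ChromaSeries]:
    """Frames + detector -> one raw ChromaSeries per ROI (gaps marked invalid)."""
    smoother = MovingAverageSmoother(cfg.maf_n, smooth_size=cfg.smooth_size)
    records: dict[str, dict[str, list]] = {}
    n_frames = 0
    n_dropout = 0
    frame_h = frame_w = None

    for k, frame in enumerate(frames):
        frame = np.asarray(frame)
        if frame_h is None:
            frame_h, frame_w = frame.shape[:2]
        n_frames += 1
        raw = detect_face(frame, detector, frame_index=k, fs=cfg.fps)
        if raw is None:
            n_dropout += 1
            log.debug("frame %d: no face detected", k)
            for rec in records.values():
                _append(rec, k, np.nan, np.nan, np.nan, False)
            continue
        box = smoother.update(raw.clamped(frame_w, frame_h))
        rois = cheek_rois(box, cfg.roi_spec, frame_w, frame_h)
        for roi in rois:
            rec = records.setdefault(
                roi.roi_id, {"frame": [], "r": [], "g": [], "b": [], "valid": []}
            )
            # Back-fill invalid samples for ROIs first seen late.
            while len(rec["frame"]) < k:
                _append(rec, len(rec["frame"]), np.nan, np.nan, np.nan, False)
            r, g, b = roi_mean_rgb(frame, roi)
            _append(rec, k, r, g, b, True)

    if n_frames == 0:
        raise ConfigurationError("empty frame sequence")
    if not records:
        raise NoFaceDetectedError(f"no face detected in any of {n_frames} frames")
    log.info("%d frames, %d dropouts (%.1f%%)", n_frames, n_dropout, 100 * n_dropout / n_frames)

    out = {}
    for roi_id, rec in records.items():
        while len(rec["frame"]) < n_frames:
            _append(rec, len(rec["frame"]), np.nan, np.nan, np.nan, False)
        out[roi_id] = ChromaSeries.from_rgb(
            roi_id, cfg.fps, rec["frame"], rec["r"], rec["g"], rec["b"], rec["valid"]
        )
    return out


def _append(rec, k, r, g, b, valid):
    rec["frame"].append(k)
    rec["r"].append(r)
    rec["g"].append(g)
    rec["b"].append(b)
    rec["valid"].append(valid)


def estimate_series(series: ChromaSeries, cfg: PipelineConfig) -> PulseEstimate:
    """Run the configured estimator on one gap-free ROI series."""
    if cfg.method == "stft":
        return stft_rate(series, cfg.band, cfg.stft)
    if cfg.method == "ica-bpf":
        return ica_bpf_rate(
            series, cfg.band, seed=cfg.ica_seed, component=cfg.ica_component,
            prominence_frac=cfg.prominence_frac,
        )
    wave = band_isolate(series, cfg.band)
    if cfg.method == "acf":
        return acf_rate(wave, cfg.band, cfg.acf, cfg.prominence_frac)
    if cfg.method == "peak-count":
        return peak_count_rate(wave, cfg.peak_window_s, cfg.band, cfg.prominence_frac)
    est = rfpr(detect_peaks(wave, cfg.band, cfg.prominence_frac))
    est.roi_id = series.roi_id
    est.window = (0.0, series.duration_s)
    return est


def run_pipeline(frames, detector, cfg: PipelineConfig | None = None) -> dict:
    """Full chain on a frame source; returns the results document.

    The document is JSON-serializable and deterministic for identical
    inputs: it records the resolved config, dropout statistics, the
    per-ROI estimates and the fused rate.  Stage timings go to the
    log, not the document.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    raw_series = extract_chroma(frames, detector, cfg)
    t1 = time.perf_counter()
    log.info("chroma extraction: %.2f s", t1 - t0)

    estimates = []
    per_roi = {}
    dropout_stats = {}
    for roi_id in sorted(raw_series):
        series = raw_series[roi_id]
        dropout_stats[roi_id] = int((~series.valid).sum())
        repaired = interpolate_gaps(series, cfg.max_gap_s)
        est = estimate_series(repaired, cfg)
        estimates.append(est)
        per_roi[roi_id] = est.bpm
    log.info("estimation: %.2f s", time.perf_counter() - t1)

    fused = fuse_weighted(estimates, list(cfg.weights) if cfg.weights else None)
    return {
        "config": cfg.to_jsonable(),
        "n_frames": int(len(next(iter(raw_series.values())).frame_index)),
        "dropouts_per_roi": dropout_stats,
        "method": cfg.method,
        "per_roi_bpm": per_roi,
        "fused_bpm": fused.bpm,
    }


def run_on_scene(scene_data, cfg: PipelineConfig | None = None) -> dict:
    """Convenience: run the pipeline on a generated synthetic scene
    with its ground-truth replay detector."""
    from .tracking import ReplayDetector

    cfg = cfg or PipelineConfig()
    if cfg.fps != scene_data.scene.fps:
        cfg = PipelineConfig(**{**cfg.__dict__, "fps": scene_data.scene.fps})
    detector = ReplayDetector(scene_data.detections)
    return run_pipeline(scene_data.frames, detector, cfg)


def write_results(results: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
        fh.write("\n")
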