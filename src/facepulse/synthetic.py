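"""Seeded synthetic pulsatile scenes and signal-level fixtures.

Every downstream stage is testable without recorded data: the
generator emits a frame sequence containing a rectangular skin-colored
"face" whose green channel oscillates at the cardiac frequency while
red and blue carry a half-amplitude anti-phase component — so Cg
(-0.25R + 0.5G - 0.25B) amplifies the pulse — plus the three noise
sources a camera in the field sees: a common-mode low-frequency
illumination drift on all channels, Gaussian per-frame jitter on the
reported face-box coordinates, and i.i.d. per-frame detection
dropouts.  Optionally a static per-pixel skin texture is painted on
the face, which converts coordinate jitter into chroma noise (the
failure mode the moving-average stabilizer exists to fix).

Identical scene parameters and seed give bit-identical frames,
detections and dropout masks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .chroma import ChromaSeries
from .errors import ConfigurationError, UnusableFixtureError
from .tracking import FaceBox, round_half_away

#: Background color (distinct from skin) for synthetic frames.
BACKGROUND_RGB = (40, 40, 48)


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth description of one synthetic facial video.

    Defaults emulate the study conditions: 60 s at 30 fps, a pulse
    whose chrominance amplitude (2 color units) is small against an
    8-unit illumination drift at 0.05 Hz, 3 px coordinate jitter and a
    5% per-frame dropout probability.  The 128x96 frame with a 64 px
    face keeps the ROI-to-face and jitter-to-face proportions of a
    typical handheld recording while staying cheap to synthesize.
    """

    pulse_bpm: float = 72.0
    fps: float = 30.0
    duration_s: float = 60.0
    frame_w: int = 128
    frame_h: int = 96
    skin_rgb: tuple[float, float, float] = (150.0, 100.0, 90.0)
    pulse_amp: float = 2.0
    drift_amp: float = 8.0
    drift_freq_hz: float = 0.05
    jitter_sigma_px: float = 3.0
    drop_prob: float = 0.05
    texture_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fps and duration_s must be positive")
        if self.pulse_bpm <= 0:
            raise ConfigurationError("pulse_bpm must be positive")
        if not 0.0 <= self.drop_prob <= 1.0:
            raise ConfigurationError("drop_prob must lie in [0, 1]")
        if self.drift_freq_hz >= 0.5:
            raise ConfigurationError("drift_freq_hz must be < 0.5 Hz")
        for name in ("pulse_amp", "drift_amp", "jitter_sigma_px", "texture_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.frame_w < 32 or self.frame_h < 32:
            raise ConfigurationError("frame must be at least 32x32 px")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def face_rect(self) -> tuple[int, int, int, int]:
        """True (x, y, w, h) of the synthetic face, centered."""
        fw = self.frame_w // 2
        fh = (2 * self.frame_h) // 3
        return ((self.frame_w - fw) // 2, (self.frame_h - fh) // 2, fw, fh)


@dataclass
class SceneData:
    """Generated scene: frames plus every piece of ground truth."""

    scene: SyntheticScene
    frames: np.ndarray  # (T, H, W, 3) uint8
    true_boxes: list[FaceBox]
    detections: list[tuple[int, int, int, int] | None]
    dropout_mask: np.ndarray  # (T,) bool, True = no detection
    truth_wave: np.ndarray  # noiseless pulsatile component, (T,)

    @property
    def t_sec(self) -> np.ndarray:
        return np.arange(self.scene.n_frames) / self.scene.fps


def generate_scene(scene: SyntheticScene, max_gap_s: float = 2.0) -> SceneData:
    """Render a scene's frames, jittered detections and dropout mask.

    Raises :class:`UnusableFixtureError` when the sampled dropout
    pattern contains a gap longer than `max_gap_s` (such a fixture
    could never survive interpolation downstream).
    """
    s = scene
    rng = np.random.default_rng(s.seed)
    T = s.n_frames
    t = np.arange(T) / s.fps
    fx, fy, fw, fh = s.face_rect

    pulse = s.pulse_amp * np.sin(2.0 * np.pi * (s.pulse_bpm / 60.0) * t)
    drift = s.drift_amp * np.sin(2.0 * np.pi * s.drift_freq_hz * t)

    # Draw order is part of the determinism contract: texture, jitter, dropouts.
    texture = (
        rng.normal(0.0, s.texture_amp, size=(fh, fw, 3)) if s.texture_amp > 0 else None
    )
    jitter = (
        rng.normal(0.0, s.jitter_sigma_px, size=(T, 4))
        if s.jitter_sigma_px > 0
        else np.zeros((T, 4))
    )
    dropout = rng.random(T) < s.drop_prob if s.drop_prob > 0 else np.zeros(T, dtype=bool)

    longest = _longest_run(dropout)
    if longest / s.fps > max_gap_s:
        raise UnusableFixtureError(
            f"drop_prob={s.drop_prob} produced a {longest / s.fps:.2f} s dropout gap "
            f"(> max_gap_s={max_gap_s}); fixture unusable"
        )

    frames = np.empty((T, s.frame_h, s.frame_w, 3), dtype=np.uint8)
    bg = np.array(BACKGROUND_RGB, dtype=np.float64)
    skin = np.array(s.skin_rgb, dtype=np.float64)
    # Anti-phase, half-amplitude R/B modulation: Cg adds the channel
    # contributions constructively while common-mode drift cancels.
    chan_gain = np.array([-0.5, 1.0, -0.5])
    for k in range(T):
        frame = np.broadcast_to(bg + drift[k], (s.frame_h, s.frame_w, 3)).copy()
        face = skin + chan_gain * pulse[k] + drift[k]
        patch = np.broadcast_to(face, (fh, fw, 3))
        if texture is not None:
            patch = patch + texture
        frame[fy : fy + fh, fx : fx + fw, :] = patch
        np.clip(frame, 0.0, 255.0, out=frame)
        frames[k] = np.rint(frame).astype(np.uint8)

    true_boxes = [FaceBox(k, t[k], fx, fy, fw, fh) for k in range(T)]
    detections: list[tuple[int, int, int, int] | None] = []
    for k in range(T):
        if dropout[k]:
            detections.append(None)
            continue
        x = round_half_away(fx + jitter[k, 0])
        y = round_half_away(fy + jitter[k, 1])
        w = round_half_away(fw + jitter[k, 2])
        h = round_half_away(fh + jitter[k, 3])
        x = min(max(x, 0), s.frame_w - 1)
        y = min(max(y, 0), s.frame_h - 1)
        w = max(1, min(w, s.frame_w - x))
        h = max(1, min(h, s.frame_h - y))
        detections.append((x, y, w, h))

    return SceneData(s, frames, true_boxes, detections, dropout, pulse)


def _longest_run(mask: np.ndarray) -> int:
    longest = run = 0
    for v in mask:
        run = run + 1 if v else 0
        longest = max(longest, run)
    return longest


def generate_cg_fixture(
    pulse_bpm: float,
    fps: float = 30.0,
    duration_s: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    amp: float = 1.0,
    roi_id: str = "ROI1",
) -> ChromaSeries:
    """Signal-level shortcut: a Cg sinusoid plus Gaussian noise.

    Bypasses frame rendering entirely; all samples valid.  The RGB
    channels are synthesized consistently (G carries the modulation)
    so the stored Cg equals -0.25R + 0.5G - 0.25B exactly.
    """
    if pulse_bpm <= 0 or fps <= 0 or duration_s <= 0:
        raise ConfigurationError("pulse_bpm, fps and duration_s must be positive")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    cg = amp * np.sin(2.0 * np.pi * (pulse_bpm / 60.0) * t)
    if noise_sd > 0:
        cg = cg + rng.normal(0.0, noise_sd, size=n)
    base = 100.0
    return ChromaSeries.from_rgb(
        roi_id, fps, np.arange(n), np.full(n, base), base + 2.0 * cg, np.full(n, base)
    )


def inject_gap(series: ChromaSeries, start_s: float, duration_s: float) -> ChromaSeries:
    """Mark one contiguous run of samples invalid (interpolation stress)."""
    t = series.t_sec
    mask = (t >= start_s) & (t < start_s + duration_s)
    valid = series.valid & ~mask
    nan = np.where(mask, np.nan, 1.0)
    return ChromaSeries(
        series.roi_id,
        series.fs,
        series.frame_index,
        series.mean_r * nan,
        series.mean_g * nan,
        series.mean_b * nan,
        series.cg * nan,
        valid,
    )


def write_scene(data: SceneData, video_path, truth_json_path=None, waveform_csv_path=None):
    """Write frames to a video container plus sidecar ground truth.

    The container format follows the file extension via imageio; a
    multi-page ``.tif`` stack is the dependable choice in minimal
    installs (MP4/AVI need an ffmpeg-backed imageio plugin).  The JSON
    sidecar records the scene parameters, seed and dropout mask; the
    CSV holds the noiseless pulsatile waveform (frame, t_sec, value).
    """
    import imageio.v3 as iio
    import pandas as pd

    iio.imwrite(str(video_path), data.frames)
    if truth_json_path is not None:
        truth = {
            "scene": asdict(data.scene),
            "dropout_mask": data.dropout_mask.astype(int).tolist(),
            "detections": [list(d) if d is not None else None for d in data.detections],
        }
        with open(truth_json_path, "w") as fh:
            json.dump(truth, fh, indent=1)
    if waveform_csv_path is not None:
        pd.DataFrame(
            {
                "frame": np.arange(data.scene.n_frames),
                "t_sec": data.t_sec,
                "value": data.truth_wave,
            }
        ).to_csv(waveform_csv_path, index=False)
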