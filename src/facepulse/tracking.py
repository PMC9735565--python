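"""Face detection and moving-average stabilization of the face box.

A face detector reports a bounding box per frame, but consecutive
detections jitter by a few pixels even for a motionless subject, which
shifts the cheek ROIs and injects high-frequency noise into the chroma
signal.  A moving average filter (MAF) over the last ``n`` raw boxes,

    x̄_k = (x_{k-n+1} + ... + x_k) / n,

suppresses that jitter; n = 15 at 30 fps (half a second of history) is
the default.  Detectors are pluggable: any callable mapping a frame to
a list of (x, y, w, h) candidates works.  A Haar-cascade detector is
provided for real videos (requires the optional ``cv2`` dependency);
a ground-truth replay detector is provided for synthetic scenes.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

DEFAULT_MAF_WINDOW = 15


def round_half_away(v: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(v + 0.5)) if v >= 0 else int(math.ceil(v - 0.5))


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face rectangle, top-left origin, y downward."""

    frame_index: int
    t_sec: float
    x: int
    y: int
    w: int
    h: int

    @property
    def area(self) -> int:
        return self.w * self.h

    def clamped(self, frame_w: int, frame_h: int) -> "FaceBox":
        x = min(max(self.x, 0), frame_w - 1)
        y = min(max(self.y, 0), frame_h - 1)
        w = max(1, min(self.w, frame_w - x))
        h = max(1, min(self.h, frame_h - y))
        return replace(self, x=x, y=y, w=w, h=h)


def detect_face(frame, detector, frame_index: int = 0, fs: float = 30.0) -> FaceBox | None:
    """Run a pluggable detector on one frame.

    The detector returns zero or more (x, y, w, h) candidates; the
    largest-area one wins (single-subject assumption: the dominant
    face is the subject).  Returns ``None`` on no detection.
    """
    boxes = detector(frame)
    if not boxes:
        return None
    x, y, w, h = max(boxes, key=lambda b: b[2] * b[3])
    return FaceBox(frame_index, frame_index / fs, int(x), int(y), int(w), int(h))


class MovingAverageSmoother:
    """Sliding-window mean over raw face-box coordinates.

    Holds the last ``window_n`` raw boxes; during warm-up (fewer than
    ``window_n`` detections so far) the mean runs over what is
    available.  Widths/heights are smoothed with the same window as
    x/y by default, since ROI geometry consumes W and H and unsmoothed
    sizes would re-inject jitter; set ``smooth_size=False`` to smooth
    only the corner coordinates.  Missing detections never enter the
    history — the smoother resumes from prior history when detection
    resumes.
    """

    def __init__(self, window_n: int = DEFAULT_MAF_WINDOW, smooth_size: bool = True):
        if window_n < 1:
            raise ConfigurationError(f"MAF window must be >= 1, got {window_n}")
        self.window_n = int(window_n)
        self.smooth_size = bool(smooth_size)
        self._history: deque[FaceBox] = deque(maxlen=self.window_n)

    def __len__(self) -> int:
        return len(self._history)

    def update(self, raw: FaceBox) -> FaceBox:
        """Append a raw detection and return the smoothed box."""
        self._history.append(raw)
        xs = np.array([b.x for b in self._history], dtype=np.float64)
        ys = np.array([b.y for b in self._history], dtype=np.float64)
        sm = dict(x=round_half_away(xs.mean()), y=round_half_away(ys.mean()))
        if self.smooth_size:
            ws = np.array([b.w for b in self._history], dtype=np.float64)
            hs = np.array([b.h for b in self._history], dtype=np.float64)
            sm.update(w=round_half_away(ws.mean()), h=round_half_away(hs.mean()))
        return replace(raw, **sm)

    def reset(self) -> None:
        self._history.clear()


def smooth_box(state: MovingAverageSmoother, raw: FaceBox) -> FaceBox:
    """Functional alias for :meth:`MovingAverageSmoother.update`."""
    return state.update(raw)


class ReplayDetector:
    """Ground-truth replay detector for synthetic scenes.

    Wraps the per-frame (box or None) detections a
    :class:`~facepulse.synthetic.SyntheticScene` generated; each call
    consumes the next frame's entry, so call it exactly once per frame
    in order.
    """

    def __init__(self, detections):
        self._it = iter(detections)

    def __call__(self, frame):
        det = next(self._it)
        if det is None:
            return []
        x, y, w, h = det
        return [(x, y, w, h)]


class HaarCascadeDetector:
    """Frontal-face Haar cascade backed by OpenCV (optional dependency)."""

    def __init__(self, cascade_path: str | None = None, min_size: tuple[int, int] = (30, 30)):
        try:
            import cv2
        except ImportError as exc:  # pragma: no cover - cv2 optional
            raise ConfigurationError(
                "Haar detection requires opencv-python (install facepulse[haar]); "
                "use ReplayDetector or another pluggable detector otherwise"
            ) from exc
        self._cv2 = cv2
        if cascade_path is None:
            cascade_path = cv2.data.haarcascades + "haarcascade_frontalface_default.xml"
        self._cascade = cv2.CascadeClassifier(cascade_path)
        if self._cascade.empty():
            raise ConfigurationError(f"could not load Haar cascade from {cascade_path}")
        self._min_size = min_size

    def __call__(self, frame):  # pragma: no cover - cv2 optional
        gray = self._cv2.cvtColor(np.asarray(frame), self._cv2.COLOR_RGB2GRAY)
        faces = self._cascade.detectMultiScale(gray, 1.1, 4, minSize=self._min_size)
        return [tuple(int(v) for v in f) for f in faces]
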