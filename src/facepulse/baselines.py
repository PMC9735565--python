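"""Comparison pulse-rate estimators: STFT, ACF, ICA+BPF, peak count.

Four alternatives to the RR-interval estimator, used as baselines:

* **STFT** — slice the Cg series into windows, take each window's
  in-band spectral argmax frequency, and average: bpm = 60 * mean(f).
* **ACF** — autocorrelate the pulse wave; periodicity shows as evenly
  spaced ACF peaks, whose mean lag spacing P gives bpm = 60 * fs / P.
* **ICA+BPF** — unmix the standardized R, G, B ROI-mean series with
  FastICA, band-pass each component (4th-order Butterworth, applied
  forward-backward for zero phase), pick the component carrying the
  most in-band power, and rate it by mean RR interval.
* **peak count** — beats counted in a window times 60/window, the
  naive short-window rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, get_window, sosfiltfilt

from .chroma import ChromaSeries
from .errors import ConfigurationError, EstimatorFailureError, NoPulseDetectedError
from .evaluation import PulseEstimate
from .pulse import (
    DEFAULT_PROMINENCE_FRAC,
    BandConfig,
    PulseWave,
    detect_peaks,
    find_peaks,
)


@dataclass(frozen=True)
class StftConfig:
    window_s: float = 10.0
    hop_s: float = 5.0
    taper: str = "hann"

    def __post_init__(self):
        if self.hop_s > self.window_s or self.hop_s <= 0:
            raise ConfigurationError(f"need 0 < hop_s <= window_s, got {self}")


@dataclass(frozen=True)
class AcfConfig:
    max_lag_s: float = 10.0
    min_lag_s: float | None = None  # defaults to 1/f_max

    def resolved_min_lag(self, band: BandConfig) -> float:
        lag = self.min_lag_s if self.min_lag_s is not None else 1.0 / band.f_max
        if lag >= self.max_lag_s:
            raise ConfigurationError(f"min lag {lag} s >= max_lag_s {self.max_lag_s} s")
        return lag


def stft_rate(
    series: ChromaSeries,
    band: BandConfig = BandConfig(),
    cfg: StftConfig = StftConfig(),
) -> PulseEstimate:
    """Mean in-band argmax frequency over sliding windows, times 60."""
    band.validate_for(series.fs)
    x = series.cg
    fs = series.fs
    win = int(round(cfg.window_s * fs))
    hop = int(round(cfg.hop_s * fs))
    if win < int(np.ceil(2.0 * fs / band.f_min)):
        raise ConfigurationError(
            f"STFT window {cfg.window_s} s too short for f_min={band.f_min} Hz"
        )
    if len(x) < win:
        raise ConfigurationError(f"series shorter than one {cfg.window_s} s window")
    taper = get_window(cfg.taper, win, fftbins=True)
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    in_band = (freqs >= band.f_min) & (freqs <= band.f_max)
    if not in_band.any():
        raise ConfigurationError(f"no DFT bin of a {cfg.window_s} s window lies in {band}")
    band_idx = np.flatnonzero(in_band)

    peaks_hz = []
    for start in range(0, len(x) - win + 1, hop):
        seg = x[start : start + win]
        mag = np.abs(np.fft.rfft((seg - seg.mean()) * taper))
        peaks_hz.append(freqs[band_idx[np.argmax(mag[band_idx])]])
    bpm = 60.0 * float(np.mean(peaks_hz))
    return PulseEstimate(
        bpm=bpm, method="stft", roi_id=series.roi_id, window=(0.0, series.duration_s)
    )


def autocorrelation(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation of a mean-removed series, lags 0..max_lag."""
    x = np.asarray(values, dtype=np.float64)
    x = x - x.mean()
    full = np.correlate(x, x, mode="full")
    acf = full[len(x) - 1 : len(x) + max_lag]
    if acf[0] > 0:
        acf = acf / acf[0]
    return acf


def acf_rate(
    wave: PulseWave,
    band: BandConfig = BandConfig(),
    cfg: AcfConfig = AcfConfig(),
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> PulseEstimate:
    """Rate from the mean spacing of autocorrelation peaks.

    Peaks are detected on the ACF for lags >= min_lag with the same
    separation/prominence criteria as pulse-wave peaks; successive
    peak-lag differences are the peak-to-peak intervals, and
    bpm = 60 * fs / mean interval.
    """
    max_lag = int(round(cfg.max_lag_s * wave.fs))
    if wave.n < 2 * max_lag:
        raise ConfigurationError(
            f"wave of {wave.n} samples shorter than 2 x max_lag ({2 * max_lag})"
        )
    min_lag = int(np.ceil(cfg.resolved_min_lag(band) * wave.fs))
    acf = autocorrelation(wave.values, max_lag)
    seg = acf[min_lag:]
    distance = max(1, int(np.ceil(wave.fs / band.f_max)))
    idx, props = find_peaks(seg, distance=distance, prominence=prominence_frac * seg.std())
    if len(idx) < 2:
        raise NoPulseDetectedError(
            f"only {len(idx)} autocorrelation peaks found; no stable periodicity"
        )
    lags = idx + min_lag
    mean_ppi = float(np.diff(lags).mean())
    est = PulseEstimate(
        bpm=60.0 * wave.fs / mean_ppi,
        method="acf",
        roi_id=wave.source_roi,
        window=(0.0, wave.duration_s),
    )
    if props["prominences"].max() < 0.2:
        warnings.warn(
            "highest ACF peak prominence < 0.2 of lag-0 power: weak periodicity, "
            "estimate may be unstable",
            stacklevel=2,
        )
    return est


def butter_bandpass_sos(band: BandConfig, fs: float, order: int = 4):
    band.validate_for(fs)
    return butter(order, [band.f_min, band.f_max], btype="bandpass", fs=fs, output="sos")


def _effective_rank(x: np.ndarray, rtol: float = 1e-8) -> int:
    sv = np.linalg.svd(x, compute_uv=False)
    return int((sv > rtol * sv[0]).sum())


def ica_bpf_rate(
    rgb_series: ChromaSeries,
    band: BandConfig = BandConfig(),
    seed: int = 0,
    component: int | None = None,
    order: int = 4,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> PulseEstimate:
    """ICA unmixing of R/G/B traces, band-pass, RR-interval rate.

    The channels are standardized (zero mean, unit variance) and
    unmixed by FastICA under a fixed seed.  Near-noiseless fixtures
    make the channel matrix rank-deficient (channels collinear), so
    the component count is reduced to the effective rank rather than
    letting whitening amplify numerical noise.  Each component is
    zero-phase Butterworth band-passed; the component with the
    largest in-band spectral power fraction (of the raw component) is
    rated, unless ``component`` forces an index.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if not rgb_series.valid.all():
        raise ConfigurationError("ICA input must be gap-free; interpolate first")
    fs = rgb_series.fs
    if rgb_series.n < 3.0 * fs / band.f_min:
        raise ConfigurationError("series too short for ICA (need >= 3 slow cycles)")
    chans = np.column_stack([rgb_series.mean_r, rgb_series.mean_g, rgb_series.mean_b])
    sd = chans.std(axis=0)
    if (sd == 0).all():
        raise EstimatorFailureError("all channels constant; nothing to unmix")
    std = (chans[:, sd > 0] - chans[:, sd > 0].mean(axis=0)) / sd[sd > 0]

    # Collinear channels (common on near-noiseless fixtures) break the
    # whitening step; project onto the full-rank subspace first.
    n_comp = _effective_rank(std)
    if n_comp < std.shape[1]:
        u, s_, _ = np.linalg.svd(std, full_matrices=False)
        std = u[:, :n_comp] * s_[:n_comp]
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica = FastICA(
                n_components=n_comp, random_state=seed, whiten="unit-variance", max_iter=500
            )
            sources = ica.fit_transform(std)
        except ConvergenceWarning as exc:
            raise EstimatorFailureError(f"FastICA did not converge: {exc}") from exc

    freqs = np.fft.rfftfreq(rgb_series.n, d=1.0 / fs)
    in_band = (freqs >= band.f_min) & (freqs <= band.f_max)
    if component is None:
        fracs = []
        for j in range(sources.shape[1]):
            power = np.abs(np.fft.rfft(sources[:, j] - sources[:, j].mean())) ** 2
            total = power[1:].sum()
            fracs.append(power[in_band].sum() / total if total > 0 else 0.0)
        component = int(np.argmax(fracs))
    elif not 0 <= component < sources.shape[1]:
        raise ConfigurationError(
            f"component index {component} out of range (have {sources.shape[1]})"
        )

    sos = butter_bandpass_sos(band, fs, order=order)
    filtered = sosfiltfilt(sos, sources[:, component])
    wave = PulseWave(fs, filtered, source_roi=rgb_series.roi_id)
    rri = detect_peaks(wave, band, prominence_frac)
    return PulseEstimate(
        bpm=60.0 / rri.mean_rri,
        method="ica-bpf",
        roi_id=rgb_series.roi_id,
        window=(0.0, rgb_series.duration_s),
    )


def peak_count_rate(
    wave: PulseWave,
    window_s: float,
    band: BandConfig = BandConfig(),
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> PulseEstimate:
    """Naive short-window rate: peaks in the window times 60/window.

    Zero detected peaks give 0 bpm with a quality warning instead of
    an error, since a short window legitimately may contain no beat.
    """
    if window_s > wave.duration_s + 1e-9:
        raise ConfigurationError(
            f"window {window_s} s longer than wave ({wave.duration_s} s)"
        )
    n_win = int(round(window_s * wave.fs))
    seg = wave.values[:n_win]
    distance = max(1, int(np.ceil(wave.fs / band.f_max)))
    sd = float(seg.std())
    idx, _ = find_peaks(seg, distance=distance, prominence=prominence_frac * sd)
    if len(idx) == 0:
        warnings.warn("no peaks in window: reporting 0 bpm (low quality)", stacklevel=2)
        return PulseEstimate(
            bpm=0.0, method="peak-count", roi_id=wave.source_roi, window=(0.0, window_s)
        )
    return PulseEstimate(
        bpm=len(idx) * 60.0 / window_s,
        method="peak-count",
        roi_id=wave.source_roi,
        window=(0.0, window_s),
    )
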