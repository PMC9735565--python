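# Methods

## Signal model

The measurable quantity is the blood-volume pulse: with each beat,
arterial blood volume in the cheek rises and absorbs slightly more
green light than red or blue. In a video at frame rate $f_s$ the
per-frame ROI-mean color is modeled as

    c(t) = c_skin + g_c · A · sin(2π f_pulse t) + D(t) + ε(t)

where the channel gains are green-dominant with an anti-phase red/blue
component ($g = (-0.5, 1, -0.5)$ up to scale), $D(t)$ is a common-mode
illumination drift shared by all channels, and $ε$ is sensor and
quantization noise. The Cg chrominance $-0.25R + 0.5G - 0.25B$ is the
linear functional that adds the channel contributions constructively
($0.75A$ for the gains above) while annihilating any common-mode term —
this, not color fidelity, is why the pipeline operates on Cg alone; the
Y and Co components are never computed.

Assumptions: a single subject facing the camera; pulse frequency
strictly inside 0.67–3.34 Hz (40–200 bpm); uniform frame timing (frame
index / fps — container timestamps are ignored); drift confined to
frequencies below the band.

## Pipeline stages and parameters

| parameter | default | units | rationale |
|---|---|---|---|
| MAF window `maf_n` | 15 | frames | half a second at 30 fps; long enough to average detector jitter, short enough to track slow head motion |
| ROI fractions | 0.3/0.7, 0.5, 0.08 | of face W/H | cheek placement over the facial artery; size tracks face *width* so ROIs stay square |
| band `f_min`–`f_max` | 0.67–3.34 | Hz | the physiological 40–200 bpm range |
| `max_gap_s` | 2.0 | s | beyond ~2 s more than a full cardiac cycle is missing at any plausible rate; a spline then invents beats |
| edge trim | 1.0 | s/side | frequency-domain masking is circular convolution; the wrap-around contaminates roughly one slow cycle at each end |
| peak prominence | 0.3·σ | of the trimmed wave | rejects ripple while keeping genuine beats whose amplitude varies |
| peak separation | 1/f_max | s | two true beats cannot be closer than the fastest period in the band |
| fusion weights | uniform (0.5/0.5) | — | no prior on which cheek is better lit; configurable per scene |

Design choices that were genuinely open, and the package's resolution:

* **Smoothing w/h.** The MAF is defined on corner coordinates; widths
  and heights are smoothed with the same window by default
  (`smooth_size=False` reverts), because ROI geometry consumes W and H
  and unsmoothed sizes re-inject jitter into ROI placement.
* **The second cheek's x offset** is `X + 0.7·W`, symmetric with the
  first; size is 8% of W for both dimensions.
* **Band edges** are inclusive: a bin exactly on f_min or f_max is
  kept. DC and Nyquist are always zeroed. The series mean is removed
  before the transform — DC is zeroed anyway, but removal reduces
  floating-point leakage. No taper is applied before the transform:
  the mask is the filter, and a taper would distort in-band amplitude.
* **Interpolation operates on Cg** (and, with the same spline
  machinery, on each RGB channel so the ICA route also sees gap-free
  input). Leading/trailing invalid runs are trimmed, never
  extrapolated.
* **Gap length** is counted as missing-samples/fs; a run longer than
  `max_gap_s` aborts with the gap's time span in the error.
* **STFT** windows are 10 s with 5 s hop and a Hann taper (the window
  length sets the 0.1 Hz = 6 bpm bin width that limits this method).
* **ACF** is computed once over the whole wave (lags to 10 s), peaks
  detected with the same criteria as pulse peaks; a best-peak
  prominence under 0.2 of the lag-0 power triggers a weak-periodicity
  warning.
* **ICA component choice**: components are not ordered, so "the green
  component" is ill-defined; the default picks the component with the
  largest in-band spectral power fraction (measured pre-filter, where
  the fraction is discriminative), overridable by index. The
  Butterworth band-pass is order 4, applied forward-backward for zero
  phase. FastICA runs under a fixed seed; collinear channels (common
  on near-noiseless fixtures) are handled by projecting onto the
  full-rank subspace before unmixing rather than letting whitening
  amplify numerical noise.
* **Rounding** of smoothed coordinates and ROI geometry is
  half-away-from-zero; ROI rectangles are half-open; plateau maxima
  resolve to the earliest sample.
* **Multiple detected faces**: the largest-area box wins (single-
  subject assumption).

## Synthetic scenes

The generator emulates exactly the structure the method assumes: a
rectangular skin patch (RGB (150, 100, 90)) whose green channel
oscillates with amplitude 2 color units at the set rate, red/blue in
anti-phase at half amplitude; an 8-unit common-mode drift at 0.05 Hz
(deliberately 4× the pulse amplitude — the raw channels are
drift-dominated, Cg is not); per-frame Gaussian jitter (σ = 3 px) on
all four reported box coordinates; and i.i.d. 5% detection dropouts.
Frames are 128×96 with a 64 px face — scaled down from a typical
640×480 recording while preserving the ROI-to-face and jitter-to-face
proportions, so the whole suite and the acceptance script run in
seconds. An optional static per-pixel texture (σ `texture_amp`,
default 0) makes coordinate jitter translate into chroma noise; the
stabilization experiments enable it at σ = 12 (a realistic
freckle/shading contrast) because on a perfectly uniform face ROI
displacement is invisible and the moving-average filter has nothing to
fix.

What the generator does **not** emulate: head pose and rotation,
specular highlights, non-sinusoidal pulse morphology (dicrotic notch),
heart-rate variability within a record, rolling-shutter artifacts, and
compression noise. Passing tests therefore demonstrate the pipeline's
signal-processing correctness and its robustness to the three modeled
noise sources — not performance on real skin in real light.

Determinism contract: one `numpy` generator seeded from the scene seed,
drawn in a fixed order (texture, jitter, dropouts), so identical
parameters give bit-identical frames, detections and masks.

## Numerical notes

* Band isolation uses the real-input FFT; conjugate symmetry is
  structural, and the reconstruction is real by construction. Against
  a brute-force full-DFT mask oracle the agreement is at machine
  precision (~1e-15 relative).
* The natural cubic spline is solved by the standard tridiagonal
  system (via `scipy.interpolate.CubicSpline(bc_type="natural")`);
  a single missing sample on a 1.2 Hz sinusoid at 30 fps comes back
  with ~1.3e-4 absolute error on unit amplitude.
* Peak times are quantized to the sample grid, so the RR-interval
  rate carries an irreducible error of order
  $\frac{60}{\overline{RRI}^2}\cdot\frac{1}{f_s\,n}$ for $n$
  intervals — this 1/n shrinkage is what the short-window experiments
  trace (error falls from ~0.13 bpm at 10 s to ~0.01 bpm at 60 s on
  mildly noisy fixtures).
* Estimation problem sizes throughout tests and the acceptance script:
  60 s records at 30 fps (1800 samples), 10 seeds for stochastic
  experiments, 5 seeds for the window sweep.

## Known limitations

* The Haar detector path requires `opencv-python` and is exercised
  only for its configuration-error contract in minimal installs; real-
  video behavior inherits the cascade's detection quirks.
* MP4/AVI export requires an ffmpeg-backed imageio plugin; the
  dependable interchange format here is multi-page TIFF.
* The ACF and STFT estimators assume a quasi-stationary rate over the
  record; strong rate drift within a record biases both.
* Fusion is a fixed-weight average; it does not detect or down-weight
  a corrupted ROI automatically.
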