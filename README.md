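# facepulse

Non-contact pulse-rate measurement from facial video, built to survive
field conditions — handheld phones, outdoor light, cars, drones — where
camera shake, illumination changes and intermittent face detection break
the usual remote-photoplethysmography (rPPG) recipes.

The package is for researchers and engineers prototyping camera-based
vital-sign measurement: it provides the full measurement chain as a
library plus a small CLI, along with a seeded synthetic-scene generator
so every stage is testable without recorded subjects.

## Method

Given a video of a face at frame rate $f_s$ (typically 30 fps):

1. **Stable face tracking.** A pluggable detector (Haar cascade for real
   video) reports a face box per frame. Raw coordinates jitter frame to
   frame, so each coordinate is smoothed by a moving average filter
   (MAF) over the last $n$ detections, $\bar{x}_k = \frac{1}{n}\sum_{i=k-n+1}^{k} x_i$,
   with $n = 15$ by default.
2. **Cheek ROIs.** Two square regions over the facial artery:
   $x_{ROI1} = X + 0.3W$, $x_{ROI2} = X + 0.7W$, $y = Y + 0.5H$, with
   width and height $0.08W$.
3. **Cg chrominance.** Per frame and ROI, the mean RGB triple is reduced
   to the YCgCo green-difference component
   $Cg = -0.25\,\bar r + 0.5\,\bar g - 0.25\,\bar b$,
   which amplifies the blood-volume pulse (green-dominant, with an
   anti-phase red/blue component) while cancelling common-mode
   illumination drift. Detection dropouts are repaired by a natural
   cubic spline ($S''(t_0) = S''(t_n) = 0$) as long as no gap exceeds
   2 s.
4. **Band isolation.** The pulse wave is cut out in the frequency
   domain: DFT of the mean-removed Cg series, zero every bin outside
   the cardiac band 0.67–3.34 Hz (40–200 bpm), inverse DFT. This
   brick-wall mask has none of the group delay or transient distortion
   of an IIR/FIR band-pass; one second is trimmed at each record edge
   to discard circular wrap-around.
5. **RR-interval rate (RFPR).** Peaks of the pulse wave give RR
   intervals $rri_i = t(\mathrm{peak}_i) - t(\mathrm{peak}_{i-1})$, and
   the robust facial pulse rate is
   $\mathrm{RFPR} = 60 / \overline{RRI}$ bpm.
   Because $\overline{RRI}$ telescopes to (last peak − first peak)/count,
   the estimate is insensitive to timing noise on interior peaks.
6. **Fusion.** Per-ROI rates are combined by a weighted average
   (default 0.5/0.5 for the two cheeks).

Three baseline estimators are included for comparison: **STFT**
(mean in-band argmax frequency over sliding windows, ×60), **ACF**
(mean autocorrelation peak spacing $\bar P$ gives $60 f_s/\bar P$), and
**ICA+BPF** (FastICA unmixing of the R/G/B traces, zero-phase
Butterworth band-pass, RR-interval rate of the most in-band component),
plus the naive peak-count rate for short windows. Estimates are scored
with MAE, RMSE, MAPE and Pearson r.

## Worked example

Generate a 60 s synthetic scene (72 bpm pulse, 3 px detector jitter,
5% dropouts, illumination drift) and measure it:

```sh
$ facepulse synth --bpm 72 --duration 60 --seed 42 --out scene.tif
wrote scene.tif (1800 frames, 72.0 bpm, 95 dropouts) + sidecars

$ facepulse run --video scene.tif --truth-json scene.truth.json --out results.json
rfpr fused rate: 71.96 bpm (per ROI: {'ROI1': 71.95767195767196, 'ROI2': 71.95767195767196})
```

The fused estimate is 71.96 bpm against a 72.0 bpm ground truth: the
95 dropout frames were spline-repaired, both cheek ROIs recovered the
rate independently, and their weighted average is within 0.05 bpm of
truth. `results.json` records the resolved configuration, dropout
statistics and per-ROI rates. The same chain is available from Python:

```python
from facepulse import SyntheticScene, generate_scene, run_on_scene

data = generate_scene(SyntheticScene(pulse_bpm=72, seed=42))
print(run_on_scene(data)["fused_bpm"])   # 71.957...
```

Use `--method stft|acf|ica-bpf` to run a baseline estimator, and
`facepulse eval --pred pred.csv --ref ref.csv` to score estimates
against a reference trace (`t_sec,bpm`, or raw `t_sec,ppg` which is
reduced to a rate by the same RR-interval machinery).

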