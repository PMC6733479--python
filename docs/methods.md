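# Methods

## The measurement and the artifact model

Pulse transit time is computed per beat as the interval from the ECG R peak
to the *pulse arrival point* of the following PPG upstroke, defined as the
instant of steepest ascent (maximum first derivative on the rising limb).
The beat-indexed series is resampled to a uniform 4 Hz grid with a natural
cubic spline so that spectral and time-frequency analysis apply.

The artifact is modeled mechanistically with a two-clock acquisition chain.
The PPG timebase runs at relative rate `1 + ε` against the ECG timebase
(`ε = drift_ppm × 1e-6`); the recorded PPG sample at nominal time `t` is the
true signal at `t + offset(t)`, where the offset grows at `ε` s/s and is
reset by one correction quantum `q` (default one nominal PPG sample period,
8 ms at 125 Hz) whenever it reaches the trigger threshold (default `q`).
The offset is therefore a sawtooth in `[0, q)` with period `T = q/ε`, and a
feature truly occurring at time τ appears in the record at `τ − offset`, so
the extracted PTT inherits `−offset(t)`: a downward 8 ms ramp with an
abrupt upward reset every `T` seconds. Presets: 80 ppm → 100 s, 106.7 ppm →
75 s, 53.3 ppm → 150 s, 800 ppm → 10 s, 0 ppm → no artifact. Correction is
modeled as an instantaneous offset reset (a dropped/held sample), not a
gradual slew, because only the former produces the abrupt-jump/linear-ramp
shape; skew is applied to the PPG channel only, since PTT depends only on
the inter-channel alignment, and one-sided drift is the minimal model.

This clock model is a *hypothesis sufficient to reproduce the phenomenology*.
The internal design of the monitors that produce such artifacts in clinical
recordings is not public, and no claim is made that this is the actual
mechanism; the model's role here is to generate ground-truth-bearing test
signals whose artifact has the observed amplitude-and-period structure.

## Synthetic data generator

One seeded `numpy` generator per simulation; per-channel sub-streams are
spawned deterministically (`SeedSequence(seed, spawn_key=(k,))`), so
identical configurations are bit-identical and channels are independently
reproducible. All timestamps are in seconds with `t0 = 0` and sample `i` at
`i/fs` (0-based).

- **Beat train.** RR(t) = 60/HR + Σ aₖ sin(2π fₖ t + φₖ) + N(0, σ_RR).
  Defaults: HR 75 bpm, respiratory sinus arrhythmia (0.25 Hz, 20 ms), a
  Mayer-band term (0.1 Hz, 10 ms), jitter σ 5 ms. Any realized RR ≤ 0 is a
  configuration error.
- **True PTT.** baseline + Σ aₖ sin(2π fₖ t + φₖ) + piecewise-linear trend.
  Defaults: baseline 250 ms, respiratory modulation (0.25 Hz, 3 ms) and a
  Mayer wave at 0.095 Hz, 2 ms — "slightly below 0.1 Hz", so the
  physiological line is distinguishable from a 0.1 Hz artifact. The Mayer
  amplitude is deliberately below the ~2.5 ms fundamental of an 8 ms
  peak-to-peak sawtooth, matching the clinical observation that the artifact
  is the dominant spectral line in most affected subjects.
- **ECG.** A Gaussian R-wave template (σ = 10 ms, amplitude 1) at each beat
  plus white noise (default SD 0.02, i.e. R dominates noise 50×; the R-peak
  detector is additionally validated at SNR 10). P/T waves, arrhythmia and
  baseline wander are out of scope.
- **PPG.** Closed-form pulse: raised-cosine upstroke of width W = 120 ms
  followed by exponential decay (τ = 300 ms). The continuous template's
  steepest ascent is analytically at W/2 after onset, so each pulse is
  placed with that point exactly at beat + true PTT — the extractor has an
  exact oracle. Upstrokes may not overlap beyond 90 % of the inter-pulse
  interval (decay tails sum freely, as in real PPG). Additive noise is
  band-limited below 10 Hz before scaling to the configured SD (default
  0.005 of the unit pulse amplitude), emulating the heavy analog filtering
  of monitor front ends; broadband white noise at the native rate would be
  unrealistic and would make the unsmoothed first-difference arrival
  detector meaninglessly noisy.
- **Clock skew.** Implemented by linear resampling of the clean PPG at the
  distorted time grid `t + offset(t)`; correction event times are returned
  and stored as ground truth.

What the generator does **not** emulate: real PPG morphology changes
(vasoconstriction, motion), ectopy and missed beats, non-constant drift
rates, or vendor-specific resampling filters. Passing tests therefore show
that the *analysis chain* behaves correctly under the stated artifact
mechanism — not that every real-world recording will be as clean.

## Extraction chain

PPG is linearly upsampled to 500 Hz (values at coincident grid points
unchanged). R peaks: 5–25 Hz band-pass, squared derivative, 150 ms
moving-window integration, threshold at 20 % of the 99th percentile with a
250 ms refractory, then refinement to the raw-ECG maximum within ±100 ms
(wide enough to absorb the integration lag of edge-truncated complexes).
The algorithm is a design choice — any detector with ≥ 99 % sensitivity and
positive predictivity on the simulated records would do.

Pulse arrival searches `(r + 100 ms, r + 700 ms]` (a physiologic PTT range),
clipped at the next beat's window so each arrival is claimed once. The
arrival is the midpoint time of the largest positive first difference;
within one native 125 Hz interval the upsampled differences are exactly
equal, and the centre of the tied run is taken, making the quantization
error symmetric (±4 ms, zero-mean). An optional 20 ms smoothing flag exists
but is off by default. Windows reaching past the record end, or windows with
no rising segment, yield missing beats; missing beats are simply absent
spline knots (no imputation). Pairs with PTT outside the window bounds are
dropped; fewer than 10 surviving beats is an error.

The 4 Hz grid is anchored at the first beat time, spacing exactly 0.25 s,
and never extrapolates beyond the last beat.

Accuracy: with PPG natively at 500 Hz and zero noise, the chain recovers the
true PTT to one sample (2 ms) at beat level; with the default 125 Hz PPG,
linear interpolation cannot restore sub-sample timing, so the per-beat error
is bounded by one native sample (8 ms) with ~3 ms SD under default noise.
The sawtooth (8 ms peak-to-peak) remains clearly resolvable against this
error because it is coherent across hundreds of beats.

## Spectral quantification

A single-taper Hann periodogram of the linearly detrended series is the
default: the distinction between 0.010 and 0.012 Hz lines needs the full
record's resolution (Δf = 0.000625 Hz at 1600 s), which Welch averaging
(available via `method="welch"`) would destroy. Linear detrending removes
the slow blood-pressure-reciprocal drift that would otherwise mask the
band. The periodogram is normalized so Σ P·Δf equals the mean square of the
tapered, detrended series (Parseval, exact to machine precision).

The dominant frequency is the band argmax in 0.004–0.15 Hz (covering all
clinically reported dominants while excluding DC, respiratory and cardiac
lines), ties toward the lower frequency. Bins are centred at the observed
artifact lines {0.0067, 0.01, 0.012, 0.0133, 0.1 Hz}; a bin is assigned when
|f − c| ≤ max(0.15 c, 2Δf), nearest centre (relative distance) winning when
tolerances overlap. Claims finer than two grid bins are refused, and a
warning is raised when the record holds fewer than three periods of the
dominant frequency (short records blur the sawtooth, as 5-minute clinical
recordings do).

Sawtooth resets are located with a matched step statistic: mean over the
8 s ahead minus mean over the 8 s behind each sample, peak-picked at
≥ half a quantum with ≥ 20 s separation. The 8 s half-window averages ~10
beats of timing noise (per-beat SD ≈ 3 ms → step noise SD ≈ 1.2 ms) while
staying far below the 75–150 s periods of interest.

## De-shape STFT

Frames are Hann-windowed (default 400 s window — four cycles at 0.01 Hz —
hop 10 s), per-frame linearly detrended, and zero-padded (FFT length chosen
so the FFT grid is at least as fine as the 512-bin output grid over
0.004–0.15 Hz). The short-time cepstrum is the inverse transform of
|STFT|^γ over frequency (γ = 0.3; the compression flattens the harmonic
amplitude decay so the quefrency comb is sharp), soft-thresholded per frame
at the 0.9 quantile of its positive-quefrency part; quefrencies beyond the
window length are discarded as unobservable. The de-shape map is
`W(t, f) = |STFT(t, f)| · U(t, f)` with `U` the thresholded cepstrum read at
quefrency 1/f.

One numerical point matters at low frequencies: near 0.01 Hz a single output
frequency bin spans ~3 s of quefrency, while the cepstral peak is only
1–2 quefrency samples wide, so point-evaluating at 1/f can miss the peak
entirely. `U` therefore takes the maximum of the cepstrum over each bin's
quefrency cell `[1/(f+Δf/2), 1/(f−Δf/2)]`, falling back to linear
interpolation where the cell is narrower than the quefrency spacing. The
residual ridge quantization from this mapping is ~1e-4 Hz near 0.01 Hz —
an order of magnitude finer than the window's Fourier resolution (0.005 Hz).

All dsSTFT hyperparameters are package defaults, exposed in
`DsstftParams`; pixel-level reproduction of any particular published figure
is not attempted. Note the default band bottom (0.004 Hz) holds only 1.6
cycles per 400 s window; the implementation warns below two cycles and
refuses below one.

Ridges are per-frame argmaxima within a band, median-smoothed over 5
frames; all-zero frames yield NaN.

## Cohort averaging

Subject TF maps are truncated to the shortest common record span (times
re-referenced to each subject's first frame; the hop must agree), each map
is normalized by its own maximum — PTT oscillation amplitudes differ across
subjects and would otherwise weight the average arbitrarily — and the
element-wise mean is taken. A rhythm produced by the shared acquisition
chain survives this average; physiological episodes with subject-specific
timing are attenuated roughly in proportion to their coincidence
probability. This contrast is the package's operational test of
"non-physiological".

## Sawtooth removal

The published removal approach for such artifacts is a manifold-learning
denoiser whose algorithm is outside this package's scope; `pttsaw.removal`
provides a transparent stand-in restricted to the constant-period case: the
detrended series is folded modulo the detected period into one-sample phase
bins (nearest-bin assignment avoids float-boundary splitting), the per-phase
median across cycles forms a zero-mean template, and the tiled template is
subtracted at the phase maximizing cross-correlation. At least three full
periods are required.

A refusal guard protects against fabricating structure: the template RMS
must exceed 1.5× the mean RMS of templates folded from random permutations
of the *residual* (series minus the candidate template). Permuting the raw
series instead would inflate the null with the artifact's own variance and
refuse genuine 8 ms artifacts over realistic noise; the residual-based null
measures exactly the incoherent variance the median fold sees. The
subtracted template is zero-mean by construction, so the artifact's constant
mean offset (half a quantum, ~4 ms) is deliberately left in place — it is
indistinguishable from a calibration constant.

## Problem sizes and determinism

The canonical simulated condition is a 1600 s record (the shortest common
span used for cohort displays of the longer clinical database) at 500 Hz
ECG / 125 Hz PPG; cohort experiments use 10–20 such subjects and the
preset-mixture experiment uses 22 (9×100 s, 4×150 s, 5×75 s, 2×10 s, 2
artifact-free), mirroring the reported distribution of the 22-subject
clinical cohort. Every stochastic element is driven by one integer seed;
identical seeds give bit-identical waveforms, reports and files.

## Known limitations

- The clock model is one sufficient mechanism, not an identified cause;
  parameter recovery on real recordings can estimate (period, amplitude) but
  cannot distinguish, e.g., sender-side resampling from receiver-side
  timestamp quantization.
- The pulse-arrival definition (maximum first difference, no smoothing)
  follows the measurement convention it models; it is not robust to PPG
  noise above ~1 % of pulse amplitude at full bandwidth.
- Template subtraction assumes a constant period and constant amplitude;
  drifting periods would smear the fold and are refused only indirectly
  (through a weak template).
- The dominant-frequency bins overlap once records are short (tolerance
  widens to 2Δf); for 5-minute records the 0.0067/0.01/0.0133 Hz bins are
  not reliably separable, which the resolution guard surfaces as warnings.
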