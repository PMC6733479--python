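# pttsaw

Clock-skew sawtooth artifacts in beat-to-beat pulse transit time (PTT)
derived from patient-monitor ECG/PPG: simulate them mechanistically, extract
PTT the way clinical studies do, quantify the artifact in the frequency and
time-frequency domains, and optionally remove it.

## Why

PTT — the interval from an ECG R peak to the arrival of the corresponding
pressure pulse at a peripheral PPG site — is a popular surrogate for pulse
wave velocity and, inversely, blood pressure. It is tempting to compute it
from the ECG and PPG channels of an off-the-shelf patient monitor, but those
monitors were not designed (or calibrated) for inter-channel timing. Clinical
recordings made this way show a striking non-physiological oscillation in
PTT: a **sawtooth** — a slow linear ramp with an abrupt reset repeating with
a nearly constant period of 75–150 s (dominant frequencies 0.0067–0.1 Hz),
with an amplitude of one PPG sample period (8 ms at 125 Hz).

A parsimonious mechanism reproduces this exactly: let the PPG acquisition
clock run at a small relative rate offset ε (ppm scale) against the ECG
clock, and let the chain correct the accumulated alignment offset by
dropping/holding one sample (quantum *q*) whenever it reaches one sample
period. The offset is then a sawtooth of amplitude *q* and period

```
T = q / ε        e.g.  0.008 s / 80e-6 = 100 s
```

which transfers linearly into the extracted PTT. `pttsaw` implements this
model end to end, with ground truth, so every stage of the analysis can be
validated against known truth.

The clinical raw data this analysis pattern comes from are deposited in
Harvard Dataverse (cited as ref 13 of the originating study; no accession ID
is printed in the text). This package works entirely from its own simulator.

## What is inside

| module | role |
| --- | --- |
| `pttsaw.synth` | paired ECG/PPG generator: beat trains with HRV, physiologically modulated PTT (respiratory ~0.25 Hz, Mayer ~0.095 Hz, slow trend), QRS/pulse templates with analytic landmarks, and the dual-clock skew model (`ClockModel`, presets for 100/75/150/10 s periods) |
| `pttsaw.ptt` | extraction: PPG linear upsampling to 500 Hz, Pan–Tompkins-style R-peak detection, pulse arrival at the maximum first difference of the PPG upstroke, pairing, 4 Hz natural-cubic-spline resampling |
| `pttsaw.spectral` | Hann periodogram (Parseval-normalized), dominant-frequency classification into the clinically observed bins {0.0067, 0.01, 0.012, 0.0133, 0.1, other}, cohort bin counts, sawtooth jump detection |
| `pttsaw.deshape` | de-shape short-time Fourier transform: short-time cepstrum of \|STFT\|^γ, soft-thresholded and read at quefrency 1/f, multiplied with \|STFT\| so only fundamentals survive; ridge extraction |
| `pttsaw.cohort` | truncation to the common time span and max-normalized averaging of TF maps across subjects |
| `pttsaw.removal` | period-synchronous template subtraction (fold modulo the period, per-phase median) with a phase-shuffled-null refusal guard |
| `pttsaw.io`, `pttsaw.pipeline`, `pttsaw.cli` | CSV/HDF5 readers and writers, YAML-configured end-to-end pipeline, `pttsaw` command-line entry point |

## Worked example

```sh
python examples/01_simulate_and_extract.py
python examples/02_spectrum_classification.py
```

prints (seed 1):

```
beats simulated/detected: 2001/2001
mean PTT extracted: 246.1 ms (true mean 250.0 ms)
per-beat recovery RMSE: 5.4 ms
clock corrections injected: 15 (every 100 s)

dominant frequency: 0.0100 Hz -> bin 0.01 (prominence 257x the band floor)
artifact jumps detected: 16, median spacing 99.8 s
```

The 3.9 ms gap between extracted and true mean PTT is the mean of the
alignment-offset sawtooth (half a quantum); the 100 s jump spacing and the
0.01 Hz dominant line are the same drift-correction cycle seen from the time
and frequency domains. `examples/03_deshape_tf.py` shows the de-shape map
collapsing the harmonic comb onto the 0.01 Hz fundamental,
`examples/04_cohort_average.py` shows that line surviving averaging across
heterogeneous subjects (the non-physiological signature), and
`examples/05_remove_sawtooth.py` removes it by template subtraction
(32x power reduction at 1/period) while refusing to touch artifact-free
recordings.

The same stages are available from the shell:

```sh
pttsaw simulate --out rec --preset skwhsmh --seed 1
pttsaw extract-ptt --in rec --out ext
pttsaw spectrum --in ext/ptt_uniform.csv --out spec
pttsaw run --out full_run --seed 1     # whole pipeline, multi-subject
```

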