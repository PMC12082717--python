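# preictal-profiler

Personalized characterization of the **preictal interval** — the stretch of
unusual brain activity that precedes an epileptic seizure — from long-term
scalp EEG. Rather than assuming every patient enters a preictal state at a
fixed time before onset, the pipeline *finds* the interval for each seizure
as a prolonged excursion of the EEG away from that patient's own seizure-free
baseline, then reports when it started, how long it lasted, which electrodes
carried it, and which signal features distinguish it.

It is written for epilepsy researchers and quantitative-EEG developers who
work with annotated long-term recordings (EDF files with seizure onset
times), and it ships a synthetic-EEG generator with known ground truth so
the entire pipeline can be exercised and validated without clinical data.

## Method

1. **Preprocessing.** Each channel is band-pass filtered to 0.5–75 Hz with a
   zero-phase linear-phase FIR filter.
2. **Windowed features.** Over 6 s windows with a 3 s hop, ten quantities are
   computed per channel: spectral entropy
   H = −Σₘ P(m) log₂ P(m) of the normalized one-sided power spectrum;
   Hjorth mobility √(var(dx)/var(x)) and complexity
   mobility(dx)/mobility(x); the Higuchi fractal dimension (slope of
   log L(k) vs log 1/k of normalized curve lengths, k ≤ k_max); the relative
   power in the delta, theta, alpha, beta and gamma bands; and the DFA
   scaling exponent (slope of log F(n) vs log n of the detrended
   fluctuation of the integrated signal).
3. **Interictal reference.** A 2 h interval ending 6 h before seizure onset
   defines the patient's baseline: per channel, the feature mean μ, a
   ridge-regularized covariance S, and the threshold L₉₉ — the 99th
   percentile of the training windows' own Mahalanobis distances
   d = √((p−μ)ᵀ S⁻¹ (p−μ)).
4. **Detection.** Every window in the 6 h before onset is scored by d. The
   preictal interval [t₁, t_L] is a span that starts and ends on
   supra-threshold windows, lasts ≥ 15 min, and whose median distance d₅₀
   exceeds L₉₉; among qualifying spans the detector keeps the one with the
   largest count of above- minus below-threshold windows.
5. **Localization.** For each channel, a logistic regression on the ten
   (baseline-standardized) features is fit on a seeded 80 % split of
   preictal-vs-interictal windows and scored by the held-out F₁ =
   2·precision·recall/(precision+recall); channels strictly above the 75th
   percentile of F₁ are selected.
6. **Feature importance.** On the best channel, the absolute logistic
   weights order the ten features; the top three are reported.

## Worked example

A synthetic 8.2 h, 4-channel recording at 128 Hz with a seizure at 8 h 3 min
and a 40 min rhythmization anomaly injected on channel Fp1, ending 20 min
before onset:

```python
import preictal_profiler as pp
from preictal_profiler.synthetic import SyntheticSpec, AnomalySpec

spec = SyntheticSpec(
    n_channels=4, fs=128.0, duration_h=8.2, seizure_onset_h=8.05,
    anomaly=AnomalySpec(start_min_before_onset=60.0, duration_min=40.0,
                        channels=("Fp1",), mechanism="spectral_tilt",
                        effect_size=4.0),
    seed=0)
rec, truth = pp.generate_recording(spec)
event = pp.SeizureEvent(onset_s=8.05 * 3600, offset_s=8.05 * 3600 + 60,
                        seizure_id="1")
config = pp.load_config(overrides={"filter": {"high_hz": 60.0}})
row = pp.run_seizure(rec, event, config)
```

prints (via the row fields):

```
detected: True
preictal_start_min_before_onset: 60.05000000000006
preictal_duration_min: 40.1
provenance_channel: Fp1
d50: 18.61720304488483
l99: 5.083328876853858
channels_selected: ['Fp1']
top3_features: ['spectral_entropy', 'hjorth_complexity', 'hjorth_mobility']
```

The detected interval starts 60.05 min before onset and lasts 40.1 min —
the injected 60-to-20-minutes-before-onset anomaly recovered to within one
window hop. Its median distance (18.6) is far beyond the baseline's 99th
percentile (5.1), the affected channel is identified, and spectral entropy
and Hjorth mobility — the features the rhythmization mechanism perturbs —
lead the importance ranking. (The 60 Hz filter edge is the scaled-rate
analogue of the standard 75 Hz band top; at 256 Hz or 512 Hz the defaults
apply unchanged.)

The same analysis is available from the shell:

```bash
preictal-profiler simulate --spec spec.yaml --out data/
preictal-profiler run --edf data/SYN0000-r1.edf \
    --annotations data/SYN0000-r1.annotations.json --out results/
preictal-profiler batch --manifest manifest.yaml --out results/
```

`run`/`batch` write `report.json` / `report.csv` with one row per analyzed
seizure (start before onset, duration, channels, top-3 features) plus
cohort summary statistics, and per-channel distance traces under
`diagnostics/` for plotting.

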