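# Methods

## The model and its assumptions

The pipeline treats preictal characterization as *personalized anomaly
detection in feature space*. For each seizure with at least 8 h of
preceding signal, a seizure-free reference stretch (the **interictal
interval**, by default 2 h ending 6 h before onset) is assumed to sample a
stationary multivariate distribution of the ten windowed features on each
channel. That distribution is summarized by its mean μ and covariance S,
and every later window is scored by the Mahalanobis distance
d = √((p−μ)ᵀ S⁻¹ (p−μ)). The working hypothesis is that preictal activity
is a *prolonged* excursion of this distance, distinguishable from the ~1 %
of baseline windows that exceed the interictal 99th percentile L₉₉ by
chance.

The Gaussian summary is used only through the quadratic form; no
distributional test is performed, so heavy tails in the features degrade
the sharpness of L₉₉ but not the validity of the ranking. Because L₉₉ is
estimated from the same windows that define μ and S, roughly 1 % of
*baseline-like* windows exceed it by construction — the detection criteria
below are designed around exactly that property.

Seizures are only analyzed when ≥ 8 h of recording precedes onset, and
within a cluster (events < 12 h apart) only the first is analyzed, applied
greedily on onset-sorted events. A record is excluded when more than 10 %
of its samples (pooled over channels) exceed the transducer's physical
maximum from the EDF header.

## Detection criteria and the interval search

A preictal interval [t₁, t_L] must satisfy: (i) median distance d₅₀ > L₉₉,
and (ii) t_L − t₁ ≥ 15 min. Two operationalizations are fixed here:

* **d₅₀ is the lower median** (order statistic at index ⌊(n−1)/2⌋). Under
  this convention "d₅₀ > L₉₉" is *exactly* equivalent to "strictly more
  than half the windows exceed L₉₉", for even and odd counts alike, which
  lets a prefix-sum scan over ±1 labels implement the criterion with no
  approximation. (With an interpolated even-count median the two can
  disagree when exactly half the windows are above.)
* **Candidate spans start and end on supra-threshold windows.** Without
  this, any strong block shorter than 15 min could be padded with
  sub-threshold neighbours into a technically qualifying 15 min span.

Among qualifying spans the detector maximizes the **excess** — the count
of above- minus below-threshold windows (the maximum-sum subarray of ±1
labels, subject to the length and endpoint constraints), with ties going
to the longer and then the later span. Maximizing *length* instead is
unstable under the ~1 % baseline false-positive rate: a single spurious
supra-threshold window up to `excess` hops away from a true anomalous
block still leaves a majority, so the longest qualifying span routinely
absorbs far-away stray windows and its edges wander by tens of minutes.
The max-excess span only absorbs an outside window when it costs at most
one sub-threshold hop, so its edges track the true block to within a
couple of hops. The scan is O(n) per channel; the test suite holds it
equal to an exhaustive search over all candidate endpoint pairs with a
direct median evaluation.

Detection runs per channel (distances from different channels are never
pooled). The record-level interval is the detected interval of the channel
maximizing d₅₀/L₉₉; all per-channel detections remain available for
diagnostics. Masked (degenerate) windows count as sub-threshold.

## Feature conventions

* Spectra are one-sided periodograms with the DC bin excluded — after
  band-pass filtering the DC bin carries only numerical residue, and
  excluding it keeps the spectral entropy of any detrended window well
  defined.
* Band powers are fractions of the one-sided power inside the analysis
  band (the filter passband, clipped to Nyquist), with half-open bins
  [f₁, f₂): shared band edges (4, 8, 13, 30 Hz) are counted once, so the
  five fractions are disjoint shares summing to ≤ 1.
* The delta band is nominally 0.4–4 Hz, but with a 0.5 Hz high-pass its
  effective support is 0.5–4 Hz.
* Hjorth derivatives are first differences without sampling-rate scaling;
  mobility is then the digital mean frequency 2·sin(ω/2) of a sinusoid at
  digital frequency ω, and complexity is fully rate-invariant.
* Higuchi's k_max defaults to 8 — at 6 s windows the log L(k) curve is
  linear over k ≤ 8 for both smooth and noise-like signals.
* DFA uses distinct integer scales log-spaced from 16 samples to a quarter
  of the window (10 scales by default), non-overlapping segments, linear
  detrending, and discards the partial trailing segment at each scale.
* All ten features are invariant to positive amplitude rescaling of a
  window, so detection is insensitive to per-channel gain.
* Flat (zero-variance) windows are masked rather than fatal and are
  excluded from model fitting and from classifier datasets.

Numerical choices: the covariance ridge is λ·trace(S)/10 added to the
diagonal, λ starting at 10⁻⁶ and escalating ×10 until the condition number
drops below 10¹⁰ (band powers are linearly constrained and
entropy/mobility strongly correlated, so S is routinely near-singular);
the trace term is floored at (10⁻⁷·feature scale)² so an exactly constant
training sample still yields ≈ 0 distances. L₉₉ uses the linear
interpolation percentile convention. The FIR band-pass is a Hamming
windowed sinc with ≈ 0.25 Hz transition, odd length, applied in one
centered FFT-convolution pass over reflect-padded signal — exactly
zero-phase for symmetric taps, with output length equal to input length so
the first and last windows survive.

## Channel selection and feature importance

Windows inside the record-level preictal interval (positive class) and the
interictal interval (negative class) are z-scored with *interictal*
statistics — without a common scale, logistic weight magnitudes are not
comparable across features — and split 80/20 (stratified, seeded). The
model is trained on the 80 % split and evaluated by the held-out F₁ with
preictal as the positive class. Channels whose F₁ strictly exceeds the
75th percentile (linear interpolation) of the F₁ distribution are
selected; ties at the threshold are excluded, and when nothing is strictly
above (all-tied scores) or fewer than four channels exist, the single best
channel is used. Feature importance refits the same seeded split on the
argmax-F₁ channel and orders features by |weight|; the logistic model uses
an L2 penalty with C = 1.0 and at most 1000 iterations, all
config-exposed. A single split per channel is the default, with the seed
recorded in the report.

## The synthetic generator

Each channel is stationary Gaussian colored noise with power spectrum
gain(f)/(1 + (f/f_knee)^β) over 0.5–75 Hz, β = 1.5, a 2 Hz knee (real
scalp spectra shoulder off below a few Hz; a divergent 1/f^1.5 down to
0.5 Hz also makes window entropy implausibly noisy), a mild Gaussian alpha
bump (gain 2 at 10 Hz, σ = 1.5 Hz), and RMS ≈ 30 µV — comfortably inside
the ±100 µV range of scalp EEG and well below the 300 µV transducer
ceiling used for the noisy-record rule. Channels are independent; signals
are deterministic given the spec seed.

The anomaly replaces the samples of a contiguous pre-onset interval on a
subset of channels with a realization of a parameter-switched spectrum
(same RMS), crossfaded over 1 s at both edges. Mechanisms, with
`effect_size` scaling the parameter change (0 reproduces the baseline
exactly):

* **spectral_tilt** — per-band rhythmization: the internal spectrum of
  every band above delta is concentrated (weight 0.2·effect_size, capped
  at 0.95) into a narrow rhythm at 0.8 of the band's width, preserving
  every band's total power. Preserving band totals is what makes the
  emergent importance ranking land on spectral entropy (down — power is
  concentrated) and Hjorth mobility (up — within-band power moves toward
  the upper edge) rather than on the band fractions, whose window-to-window
  variance is far smaller; a naive whole-spectrum flattening is dominated
  by the gamma fraction instead. The delta band keeps its shape so the
  slow dynamics that DFA measures stay baseline-like. Physiologically this
  mimics preictal rhythmization rather than broadband power change.
* **band_shift** — theta gain ×(1 + 0.6·effect_size), alpha gain divided
  by the same factor: power moves between two bands.
* **entropy_drop** — a narrow 10 Hz peak (σ = 0.5 Hz) carrying
  effect_size × the broadband power: concentration that lowers entropy.

At effect_size 4 (the calibrated scale) the spectral_tilt displacement
drives essentially all in-anomaly windows past L₉₉ (measured ≥ 80 % on
every seed tested, typically 100 %), which is what gives ±1-hop edge
recovery.

What the generator does *not* emulate: eye-blink/muscle/electrode
artifacts, inter-channel correlation and volume conduction, sleep-wake
spectral cycling, and any non-Gaussian temporal structure. Passing tests
therefore demonstrate that the *pipeline* recovers known spectral-regime
changes under stationary colored noise — not that real preictal activity
takes this form, nor how the method behaves under diurnal nonstationarity,
which on real data is the main confound.

## Problem sizes in tests and the acceptance script

Cohort-level test runs use 8.2 h recordings at 128 Hz with 1–4 channels
and a 0.5–60 Hz analysis band (the scaled-rate analogue of the 75 Hz band
top; 60 Hz keeps the band below the 64 Hz Nyquist). All temporal
parameters — 6 s/3 s windows, 2 h interictal ending 6 h before onset, 6 h
search span, 99th percentile, 15 min minimum — are at their standard
values, so window counts per stage match a full-rate run. The generator's
own defaults (19 channels, 256 Hz, 9 h) describe a full-scale clinical
recording and are what the CLI `simulate` emits without a spec. Numba, when
importable, compiles the Higuchi and DFA inner loops; the numpy fallbacks
produce identical values and the suite asserts batch-equals-per-window
regardless of path.

## Known limitations

* The record-level interval comes from a single best channel; a
  multivariate combination across channels might time intervals
  differently on real data.
* L₉₉ assumes the interictal reference is representative; drowsiness or
  medication changes inside the reference window shift the threshold.
* A single 80/20 split makes F₁ scores seed-dependent near ties; the
  repeated-split stability mode is deliberately off by default to keep the
  reported numbers reproducible from one seed.
* Overlapping windows make adjacent distances correlated; L₉₉ is a
  marginal, not family-wise, threshold. The interval criteria (majority
  over ≥ 15 min) are what control false detections, as the null-specificity
  tests verify empirically.
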