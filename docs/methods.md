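# Methods

## The problem

A ballistocardiogram (BCG) records the recoil of the body as the heart ejects
blood; embedded in a chair it enables unobtrusive cardiac monitoring. Most
BCG feature-extraction algorithms assume the resting waveform of a subject is
stable from beat to beat. That assumption was established in young healthy
adults; in heart-failure (HF) patients the resting waveform can fluctuate,
which corrupts any feature keyed to a fixed morphology. This package
implements a statistic that quantifies that fluctuation — the **waveform
fluctuation metric at rest (WFMR)** — together with the full processing chain
around it and a cohort comparison between a clinical (HF) and a non-clinical
population.

## The metric

Within a 20-s epoch, a window of length `T_EA` slides in 1-s steps. The
700-sample (700 ms at 1000 Hz) heartbeats cropped from each R wave inside a
window are ensemble averaged,

    f_EA(t) = (1/N_EA) Σ_i f_i(t),   t = 1..700.

Window starts are `k = 0 .. (20 − T_EA − 1)`; the window whose end would
touch the epoch boundary is not generated, so a densely-beaten epoch yields
`20 − T_EA` ensemble averages (12 at 8 s, 15 at 5 s). Windows holding exactly
the same beat set as an earlier window are counted once; empty windows are
dropped. The discrepancy between two ensemble averages is the plain sum of
squared differences,

    MSE(f, g) = Σ_t (f(t) − g(t))²,

deliberately without the 1/n: the crop length is a constant 700, so a true
mean would only shift every WFMR by ln 700, which cancels in any comparison.
The epoch's WFMR is the natural log of the mean over all non-diagonal pairs,

    WFMR = ln( (1/(N(N−1))) Σ_{i≠j} MSE_ij ),

floored inside the log at ε = 1e−12 so a perfectly repeating beat gives a
finite (very negative) value instead of −∞. The mean over ordered and
unordered pairs coincides by symmetry. The metric is invariant to permuting
or uniformly shifting the waveforms and obeys the scale law
`WFMR(a·f) = WFMR(f) + 2 ln a`.

The window size is chosen from the sweep `T_EA ∈ {2..15}` s: per-subject
epoch means are averaged, then averaged across subjects (equal subject
weights regardless of epoch count), and the elbow of the resulting curve is
taken. The elbow rule: the first point whose following marginal decrease
drops below 10% of the total decrease, *after* at least one steep marginal —
a flat curve returns the smallest window (nothing to trade off), a curve
with no steep segment never levels off and returns the largest.

## Signal chain

* **Resampling** — polyphase band-limited resampling brings a 1024-Hz ECG to
  the common 1000-Hz rate.
* **FIR filtering** — 2-Hz high-pass (Hamming window, 1001 taps) removes
  offset and drift on all channels; 25-Hz low-pass cleans the BCG; 40-Hz
  low-pass cleans the non-clinical ECG. Filters are applied zero-phase
  (symmetric taps, centred convolution on reflection padding) so fiducial
  times and the 700-sample crop alignment are untouched; the cost is nothing
  since windowed-sinc designs are already linear-phase.
* **SWT denoising** — clinical ECGs often carry pacemaker stimulus spikes
  that a low-pass filter would destroy, so they are denoised instead with a
  5-level stationary wavelet transform (db5) and per-level soft thresholds.
  Thresholds are tuned by per-level grid search (20 candidates spanning
  [0, 3·MAD] of that level's detail coefficients, coarse levels first)
  maximising a ground-truth-free SNR proxy — RMS within ±60 ms of the R
  peaks over RMS of the isoelectric segment [R+450 ms, next R−300 ms] —
  subject to the QRS-region RMS changing by less than 5%. A nonzero
  threshold must buy at least a 2% relative SNR gain: the isoelectric window
  always contains a sliver of genuine T-wave tail, and without the margin a
  noise-free record would harvest that leakage with tiny spurious
  thresholds. The approximation subband is never thresholded (standard
  practice), so even infinite thresholds leave ~3% of white-noise variance.
  In the pipeline, thresholds are tuned on the first minute of the recording
  and applied to the whole channel.
* **Synchronization** — two ECG streams are aligned by cross-correlating
  their RR-interval sequences over integer beat lags and refining the best
  lag to a time offset (median of matched R-time differences). Paced rhythms
  with invariant RR carry no alignment information and raise a
  degenerate-input error.
* **R detection** — simplified Pan–Tompkins: 5–15 Hz band-pass, derivative,
  squaring, 150-ms integration, adaptive signal/noise-peak threshold, 250-ms
  refractory, then localization to the raw-ECG maximum within ±50 ms.
* **Beat typing** — rule-based surrogate for expert labels: *paced* if a
  narrow (<10 ms) spike at ≥5× the local baseline amplitude (and ≥20% of the
  R amplitude, so quiet baselines cannot mint spikes from noise) sits
  40–100 ms before the QRS, with candidate regions measured on a wider
  segment so a wide-QRS upstroke clipped at the window edge is not mistaken
  for a spike; *PVC* if the 20%-amplitude QRS extent is ≥120 ms without a
  spike; otherwise *intrinsic*.
* **Epoch placement** — dominant type is the record majority (ties go to
  intrinsic). 20-s windows on a 1-s grid are taken greedily left-to-right if
  they are pure (dominant-type beats only) and hold ≥8 beats; if fewer than
  five pure windows exist, the least-contaminated windows fill the quota and
  their non-dominant beats are excluded. Beats belong to a window by the
  half-open rule `start ≤ R < end`; the crop may extend past the window end.
  The ≥8-beat minimum guarantees every 8-s ensemble window holds at least
  one beat.

## Reference features

From the ECG: RR, QRS (= S − Q), `QT_BASE` (= T-end − Q), `QT_QRS`
(= `QT_BASE` minus the part of QRS above 120 ms), and the linear heart-rate
correction `QT_c = QT + 0.154 (1 − RR)` with RR and QT in seconds (the
0.154 constant is the Framingham slope, defined for seconds). Delineation is
rule-based: Q is the last return within 5% of the R amplitude in the 80 ms
before R; S is the first *sustained* return after R (within 2× the level for
8 ms — a plain first crossing would call the brief zero crossing inside a
wide slurred PVC complex the S point); T-end comes from the tangent method,
fitting a line over the 70%→30%-of-peak downslope of the
Savitzky–Golay-smoothed T wave and extending it to baseline (a one-sample
steepest tangent is far too noise-sensitive). Beats with indeterminate
fiducials are excluded from interval features only.

Beat-to-beat blood pressure from a continuous device is shifted onto the
cuff scale: for each per-minute cuff reading, the device samples of the
preceding minute are averaged, the cuff-minus-device differences (five in a
5-min recording) are averaged into one constant added to the whole series;
SBP and DBP separately.

Per-beat features are then windowed with the *same* window enumeration as
the WFMR ensembles (shared code, so counts agree by construction): window
means, epoch mean and SD of those means, each natural-log transformed, SD
floored at ε before the log.

## Cohort comparison

Per-epoch WFMR values (five per subject) are compared with a one-sided Welch
t-test (H1: clinical mean higher, Satterthwaite df) and by
leave-one-subject-out classification — naive Bayes, unpenalized logistic
regression, and a decision tree whose "maximum splits" parameter caps the
internal split nodes (`max_leaf_nodes = splits + 1`), swept over 5–30.
Accuracy is epoch-level (correct epochs / total epochs); a subject counts as
misclassified when a majority of its epochs are, ties counting as
misclassified. Folds never contain any epoch of the held-out subject.

A note on permutation nulls: at this sample size, LOSO with permuted labels
scores systematically *below* the majority-class rate, because removing a
subject tips the training balance toward the opposite class. Tests therefore
assert only that permuted labels cannot beat the baseline.

## Synthetic data

No recordings are distributed with the study, so validation runs against a
bundled generator emulating a five-minute stationary sitting recording at
1000 Hz:

* **BCG** — each beat is a sum of Gaussian bumps digitizing the canonical
  H/I/J/K/L/M/N sequence (J the largest positive wave, all centers within
  the 0.7-s crop), subjected per beat to a lognormal amplitude scale
  (σ = amplitude jitter), independent Gaussian per-component timing shifts
  (phase jitter), an AR(1) walk on component gains (shape drift), and
  sinusoidal respiratory amplitude modulation; plus white noise and sub-Hz
  baseline wander.
* **ECG** — Gaussian-bump surrogates per beat type: intrinsic (P-QRS-T),
  PVC (wide ≥120 ms QRS, no P, discordant T), paced (2.5-unit stimulus
  spike 60 ms before a widened QRS). Ground-truth Q/S are the 5%-of-R
  crossings of the spike-free complex (S sustained, as above); ground-truth
  T-end is the analytic tangent point `center + 2σ` of the Gaussian T wave.
* **BP** — true beat-to-beat SBP/DBP follow an AR(1) (φ = 0.95) around the
  subject mean; the device series adds a constant offset and noise; cuff
  readings are per-minute means of the true series.
* **RR process** — i.i.d. Gaussian jitter around 60/HR, floored at 0.35 s.
  No long-range heart-rate-variability model: the metric under study does
  not depend on one.

Cohort profiles live in `src/wfmr/profiles.yaml`: each parameter is a fixed
value or a `[low, high]` range drawn uniformly once per subject. The
clinical profile draws from wider jitter priors (amplitude jitter 0.15–0.35
vs 0.03–0.07, phase jitter 10–30 ms vs 2–6 ms, shape innovation 0.05–0.12 vs
0.01–0.03), allows sporadic PVCs (0–6%), and makes 30% of subjects
pacemaker-dominant. These values are chosen to reproduce the *qualitative*
clinical/non-clinical contrast — the study reports no quantitative jitter
distributions — and are deliberately not calibrated to any published effect
size; under them the cohorts separate almost completely, which is stronger
than the ~82–84% accuracy reported on real recordings.

What the generator does **not** emulate: hemodynamics (no physical chair
model), motion artifacts, powerline interference, electrode noise,
heart-rate-variability spectra, or any causal link between ECG conduction
intervals and BCG fluctuation. Passing tests therefore demonstrate that the
pipeline recovers known ground truth under controlled corruption — not that
it would reach the same numbers on clinical recordings.

## Replicate studies and problem sizes

Power and classification reliability are estimated on simulated cohorts of
29 non-clinical + 26 clinical subjects with five epochs each — the study's
design. The replicate path synthesizes and band-filters only the BCG and
uses the generator's beat times in place of ECG detection (detection quality
is validated separately); the WFMR computation itself is the production code
path. The test suite uses 100 replicates for the Welch power estimate and 20
for LOSO; the acceptance script uses the same sizes.

## Numerical choices

* ε = 1e−12 floors every log (WFMR and log-SD of windowed features).
* Duplicate windows compare admitted-beat index sets exactly.
* The WFMR pairwise sum uses the Gram identity
  `MSE_ij = ‖f_i‖² + ‖f_j‖² − 2⟨f_i, f_j⟩`; tests pin it to a naive double
  loop at 1e−9 relative.
* The crop is fixed at 700 samples and asserts fs = 1000 Hz rather than
  scaling with the rate.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical configuration reproduces
  byte-identical outputs.

## Known limitations

* The delineator and beat-typing rules are tuned to the generator's beat
  vocabulary; real ECG morphologies (bundle-branch blocks, fusion beats,
  atrial arrhythmias) would need a trained segmenter.
* The SNR proxy used for threshold tuning needs detectable R peaks and a
  quiet diastole; it is undefined for continuous artifacts.
* WFDB input is not supported; records are directories of delimited-text
  channels with a `# fs=` header.
* Frequency-domain variants of the fluctuation metric and sub-typing the
  fluctuation by source (amplitude vs phase) are out of scope.
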