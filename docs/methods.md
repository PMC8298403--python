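# Methods

This note documents the models, defaults, and design decisions behind
`emgesture`: what the synthetic data emulate, how each analysis stage is
defined, and where the design was genuinely open.

## Study design being analysed

The pipeline targets cued finger-movement sEMG experiments: 12
participants, an 8-bipolar-channel electrode matrix on the forearm (flexor
side in one session, extensor side in the other), 2 kHz sampling.  Each
session contains 8 movements (6 individual finger movements + 2 control
hand movements, codes 7–8) × 5 repetitions; each repetition is 5 s of
contraction followed by 5 s of rest.  Annotations carry the nominal audio
cue times; the actual contraction is shifted by the participant's reaction
time.  Control movements are simulated and stored but excluded from the
similarity and classification analyses, which use the 6 finger movements
only.

## Synthetic cohort generator

Surface EMG is modelled as zero-mean Gaussian noise spectrally shaped to
20–300 Hz (band-pass-filtered white noise), the standard phenomenological
surrogate for interference EMG.  Channel `c` of movement `m` is
amplitude-modulated during the contraction by
`spatial_gain[m, c] × participant_gain × amplitude_mv`, with 100 ms
raised-cosine on/off ramps.  On top of the modulated EMG sit:

* an EMG-band noise floor (`noise_floor_mv = 0.3` mV RMS), everywhere;
* a common-phase 50 Hz sinusoid (`powerline_amp_mv = 0.2` mV), everywhere;
* per-channel low-frequency (< 10 Hz) drift (`drift_amp_mv = 0.15` mV RMS).

With `amplitude_mv = 1.0` mV these defaults put the band-power SNR
(10 log₁₀[(P_task − P_rest)/P_rest] over 15–250 Hz) around 5–6 dB —
deliberately low-SNR recordings, consistent with printed-electrode
hardware.  Between-participant amplitude spread is LogNormal(0, 0.2), drawn
once per participant and reused across that participant's sessions.

**Trial layout.**  Each 10 s trial block is: 1 s rest (`pre_rest_s`), cue at
t = 1 s, contraction at cue + jitter lasting 5 s, remaining rest to t = 10 s.
The pre-cue rest gives onset detection a baseline and makes room for
anticipatory (negative-jitter) contractions.  Reaction-time jitter is
Gaussian with SD 0.3 s, truncated at ±3σ — untruncated tails would
occasionally push a contraction out of its block, which is not a plausible
reaction time.  A `SimulationError` is raised if a configured jitter SD
cannot fit the layout.  Annotations record only the nominal cue times, so
segment extraction must re-align, as with real data.

**Spatial profiles.**  The six finger movements get smooth unimodal gain
bumps over the 8 channels: Gaussian bumps of width 1.1 channels centred at
channels 0.0, 1.6, 3.2, 4.8 for movements 1–4 and at 6.9, 7.3 for the two
thumb movements (5–6), whose profiles therefore overlap heavily and are
nearly rank-identical — mirroring the anatomical fact that both recruit
the thumb musculature.  A gain floor of 0.15 plus a linear tilt of 0.2
across channels keeps all 8 channels at distinct, noise-robust activation
levels, so channel rankings (the quantity the Spearman analysis uses) are
stable across repetitions.  These geometry constants were fixed once, from
an analytic rank-stability model of the measured RMS patterns, before the
cohort-level validation was run.  Control movements use broad cosine
profiles activating all channels.

**What the generator does not model:** motor-unit action potentials and
their firing statistics, electrode-skin impedance variation, fatigue
drift within or across repetitions, cross-talk correlation between
channels, movement artifacts time-locked to the contraction.  Passing the
recovery tests therefore shows the analysis correctly extracts the
structure this generative model encodes — not that it is robust to every
property of real recordings.

## Preprocessing

* **Band-pass 10–380 Hz.**  Default design is a Hamming-windowed sinc FIR
  with 401 taps (0.2 s at 2 kHz) — long enough to realise the 10 Hz low
  edge.  The symmetric impulse response is applied in a single pass with
  exact group-delay compensation (linear phase ⇒ integer delay), which is
  exactly zero-phase and O(N log N) on long recordings; reflection padding
  suppresses edge transients.  A 4th-order Butterworth applied
  forward-backward (`sosfiltfilt`) is available as a config switch.
* **Notch 49–51 Hz.**  4th-order Butterworth band-stop, forward-backward.
  Contract: ≥ 20 dB attenuation at 50 Hz, ≤ 3 dB at 60 Hz.
* **Order.**  Band-pass then notch; both are zero-phase LTI operations so
  the order does not affect the result.
* **Envelope.**  Rectification followed by a centred 100 ms moving average
  (shrinking windows at the edges).  Used for onset detection and
  visualisation only — features are computed on the unrectified filtered
  signal.
* **Onset detection.**  The cross-channel summed envelope is compared to a
  threshold of rest-mean + 3 × rest-SD, where the rest statistics come from
  the trial's own rest tail (1.5 s after cue-off to 1.5 s before the next
  cue, keeping clear of jitter-shifted contractions on both sides; the
  pre-cue second is the fallback).  The onset is the first sample within
  [cue − 1 s, cue-off] that stays above threshold for ≥ 200 ms.  The 3 s
  feature segment starts 0.25 s after the onset (guard against ramp
  transients).  If no sustained crossing is found, or the detected onset
  leaves less than 3 s before cue-off + 1 s slack, the segment falls back
  to the cue-anchored position with a warning — a repetition is never
  dropped.  On the default simulator the detector locates onsets with a
  90th-percentile error under 150 ms.

## Feature bank

Eleven features per channel per 1 s non-overlapping window; a 3 s segment
yields 3 windows × 88 features.  Column order is feature-major
(`MAV_ch1..MAV_ch8, …, MDF_ch1..MDF_ch8`) and stable.

* Time domain: MAV (mean |x|), MAX, MIN, RANGE, RMS, VAR and STD (sample,
  1/(N−1)), ZC (strict sign products x_i·x_{i+1} < 0 — zeros do not count,
  no amplitude deadband), WFL (Σ|x_{i+1} − x_i|).  Sums run over
  consecutive sample pairs (N − 1 terms).
* Spectral: Welch periodogram with 1 s Hamming window, 50 % overlap,
  zero-padded to a 2048-point FFT (bin spacing 2000/2048 ≈ 0.9766 Hz at
  2 kHz), restricted to 20–300 Hz.  MNF is the spectral centroid
  Σ f·PSD / Σ PSD; MDF is the smallest bin frequency at which the
  cumulative spectrum first reaches half the total power (the discrete-bin
  convention for the equal-power split; at discrete bins the two half-sums
  cannot be made exactly equal, so a tie-break rule is required).
* Degenerate windows whose spectrum carries no power are rejected with a
  warning rather than emitting NaNs.
* Band power is the trapezoidal integral of the PSD over 15–250 Hz; SNR per
  repetition is 10 log₁₀[(P_task − P_noise)/P_noise] on band powers of the
  task window vs the adjacent rest window, with a −∞ sentinel (and warning)
  when task power does not exceed rest power.

## Similarity statistics

For each participant × finger movement, the 15 windows' 8-channel RMS
vectors are block-normalized by the maximum over all 15 × 8 values, giving
patterns x_{i,m}(k) ∈ [0, 1]⁸.

* **Spearman correlation** uses average ranks for ties (Pearson of ranks;
  equal to 1 − 6Σd²/(n(n²−1)) when ties are absent).  A constant vector has
  no rank ordering: the coefficient is NaN with a warning, and undefined
  pairs are excluded (and counted) in aggregates.
* **Intra-subject similarity**: mean over all 105 unordered pattern pairs
  of a block; 72 aggregates per session kind at full cohort size.
  Significance per block is a one-sided one-sample t-test (H₀: mean ≤ 0)
  over the 105 pairwise coefficients.  The pairwise coefficients of a block
  are not independent (they share patterns), so the p-values are
  descriptive rather than exact; no multiple-testing correction is applied
  by default (a Benjamini–Hochberg helper can be layered on by users via
  `statsmodels` if desired).
* **Intra-task (inter-subject) similarity**: each subject's 15 patterns are
  averaged into one 8-vector and renormalized; the coefficient per movement
  is the mean pairwise Spearman correlation over subject pairs.  Averaging
  before correlating (rather than pooling all windows) weights every
  subject equally.
* **Dissimilarity**: 1 − r between per-participant mean patterns of two
  movements; a 6 × 6 symmetric matrix per participant with zero diagonal
  and entries in [0, 2].  Entries above 0.2 flag robustly distinct
  movements.  Renormalizing the mean patterns has no effect on Spearman
  ranks and is done only for presentational consistency.

## Classification

Flexion and extension sessions are separate six-class problems.  Split:
repetitions 1, 2, 4, 5 of every movement from all participants train;
repetition 3 is the held-out test set (864 train / 216 test rows at full
cohort size).  Hyperparameters are selected by mean accuracy in stratified
10-fold CV on the training set over fixed, documented grids:

* DA: linear vs quadratic discriminant (QDA with a small covariance
  regulariser, 1e-3, for numerical stability on folds);
* SVM: linear / polynomial (degree 2, 3) / RBF kernels, box constraint
  C ∈ {0.1, 1, 10, 100}, RBF γ ∈ {scale, 0.01, 0.1};
* kNN: k = 1..25, Euclidean distance.

SVM and kNN operate on z-scored features (training-set statistics only,
inside the fitted pipeline, so no information leaks from the test set);
DA is scale-equivariant and runs on raw features.  The grid (rather than a
black-box optimiser) keeps tuning reproducible under a seed.

Metrics are macro-averaged over the C = 6 classes from the test confusion
matrix (rows = true, columns = predicted):

* accuracy = (1/C) Σᵢ (tpᵢ + tnᵢ)/N — the per-class-averaged accuracy;
  the conventional trace/N accuracy is also reported
  (`overall_accuracy`) since the averaged form is systematically higher
  for C > 2;
* precision = (1/C) Σᵢ tpᵢ/(tpᵢ + fpᵢ) (a never-predicted class
  contributes 0 with a warning); a historically printed variant that
  replaces precision with the per-class error rate (fpᵢ + fnᵢ)/N is
  available behind `printed_precision_form=True` for fidelity experiments
  only — it is not a precision;
* recall = (1/C) Σᵢ tpᵢ/(tpᵢ + fnᵢ); macro-F1 = 2·p_M·r_M/(p_M + r_M).

## File formats

* **EDF+** for sessions: a minimal writer/reader pair supporting ASCII
  headers, int16 data records with per-channel physical scaling (round-trip
  error bounded by range/65535), and one annotation channel carrying cue
  TALs.  The true sample count is stored in the reserved header field so
  the padded final record can be trimmed on read; MNE's EDF reader is used
  as an independent cross-check in the test suite.
* **Delimited text** everywhere else: sessions as one-sample-per-row CSV
  with a `#` metadata line and a sidecar annotation table; feature
  matrices as CSV with 4 label columns + 88 feature columns; all similarity
  and classification outputs as CSV tables.  Figures are views: every
  rendered figure has a sidecar CSV that regenerates it exactly.

## Problem sizes and determinism

The validation suite exercises the full 12-participant cohort at one
session kind for the structural and recovery checks (five generator seeds
for the recovery properties), and a 4-participant cohort across three
nuisance-amplitude levels (×1, ×0.5, ×0.1) for the noise-monotonicity
property.  The acceptance script runs both session kinds at full cohort
size.  All stochastic stages (cohort generation, CV shuffling) derive from
explicit integer seeds; a fixed seed reproduces every number bit-for-bit.

## Known limitations

* The generator's phenomenological EMG model (see above) cannot certify
  robustness to physiological or hardware effects it does not contain.
* Onset detection assumes the rest phases are genuinely quiet; tonic
  activity between trials would inflate the baseline and delay detections.
* The t-test on pairwise similarities treats dependent values as a sample;
  its p-values are descriptive.
* EDF support covers the continuous (EDF+C) subset used here — one
  annotation stream, uniform record duration — not the full EDF+ zoo.
* Classification pools all participants (subject-generalising split by
  repetition, not leave-subject-out); per-subject classifiers are out of
  scope.
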