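# Methods

## Model and assumptions

The pipeline assumes simultaneously sampled ECG, SCG, BCG (via a 3-axis
accelerometer), and PPG at a common rate (2 kHz by default), with contiguous
state annotations (NV, RH, AH) per recording and one recording per subject.
Classification is per cardiac beat, in temporal order: the two binary
stages are developed independently (stage 2 on ground-truth hypovolemia
beats, not on stage-1 predictions) and composed at prediction time through
their smoothed scores. The smoothing step assumes state episodes are long
relative to the smoother windows; it trades transition latency for
robustness to isolated misclassified beats.

## Signal processing choices

* **Filtering.** Kaiser-window FIR band-pass, 60 dB stop-band attenuation,
  0.5 Hz transition width (≈14,500 taps at 2 kHz). Zero phase is achieved by
  a single centered convolution with the symmetric (linear-phase) kernel on
  a reflect-padded signal, computed by FFT — identical net phase (zero) to
  forward–backward filtering but with one design and O(n log n) cost. The
  input mean is removed first; DC lies outside every passband, and explicit
  removal makes the rejection exact rather than bounded by the stop-band
  ripple. Signals must be longer than 3× the kernel (~22 s at defaults).
* **R detection.** Local maxima above 0.5× the rolling 5-s signal maximum,
  with a 250 ms refractory period. Both parameters are exposed; the defaults
  are adequate for clean 2 kHz ECG. Beats with RR outside [250, 2000] ms are
  discarded as missed/double detections.
* **BCG rotation.** Gravity is estimated as the mean of the raw 3-axis
  signal over the leading 10 s; the output axis is the nominal
  superior–inferior axis minimally rotated (Rodrigues) into the plane
  orthogonal to gravity. Rotation precedes filtering because the gravity DC
  component must still be present.
* **Fiducial windows** (ms after R, configurable): AO [10, 160],
  AC [200, 450], H [30, 200], then each BCG wave within a bounded offset of
  the previous one (I ≤ H+120, J ≤ I+120, K ≤ J+120, L ≤ K+150), with the
  alternation H > I < J > K < L verified. Beats with any unresolved fiducial
  contribute no feature row — dropping avoids fabricating values and the
  rate is observable per subject.

## Feature definitions

* HRV estimators, all over the same causal 100-beat window used for BCG
  variability (one windowing convention throughout): SDNN (population
  standard deviation of RR), Poincaré SD1 = std(ΔRR)/√2, and LF/HF with
  LF = [0.04, 0.15) Hz, HF = [0.15, 0.40] Hz integrated from a Lomb–Scargle
  spectrum of the (unevenly sampled) RR tachogram. Population (ddof = 0)
  standard deviations are used so closed forms such as SD1 = 100/√2 ms for a
  ±100 ms alternating series hold exactly.
* The I-K exclusion applies to the variability features only: instantaneous
  I-K interval and amplitude exist, their 100-beat standard deviations do
  not. This is the only reading consistent with the 4/13/1/28 = 46 feature
  partition.
* BCG amplitudes are the filtered-signal values at each wave (zero-mean by
  filtering, so no per-beat baseline is subtracted).
* Baseline normalization divides every feature by the subject's own mean
  over normovolemic beats; it uses no other subject's data, so no
  cross-subject leakage is possible by construction. A zero baseline mean
  invalidates that feature for that subject (warning, NaN).
* The first 100 beats of each subject have undefined windowed features and
  are excluded; windowed features are strictly causal (truncating the
  future never changes past rows — asserted by test).

## Classifier and development

* Stage-1 default: random forest with 672 estimators, maximum depth 10,
  minimum split 10, minimum leaf 2 (Gini); the pre-search initial setting
  (100, 12, 2, 1) is also exposed. Stage-2 default: L2 logistic regression,
  C = 1. SVM (RBF, C = 1, gamma = "scale") is available as a candidate.
* Scores for smoothing are class-1 probabilities (forest vote fraction, LR
  sigmoid); margin classifiers without probabilities use a
  sigmoid-transformed decision function so the smoothed mean is continuous.
* Smoothers are causal trailing means (windows 500 and 50 beats) with a
  shrinking warm-up window — deployable in real time, unlike centered
  smoothing which would need future beats. Stage-2 scores are computed and
  smoothed over all beats so the window has no gaps, and read only where
  stage 1 says hypovolemia. The 0.5 threshold is fixed by design.
* Wrapper selection is sequential forward selection scored by inner LOSO of
  the candidate classifier itself, stopping tolerance 0.002, at most 15
  features — the simplest wrapper variant with bounded runtime. Stage 1
  selects on per-subject 1:1 undersampled data (the stated imbalance is
  ~10:1) optimizing F1; stage 2 uses no resampling and optimizes accuracy.
  The final stage-1 classifier is nevertheless fitted on all training rows.
* Random search draws 60 settings by default (log-uniform for continuous
  ranges), deterministically per seed; ties prefer fewer trees / stronger
  regularization. The ranges contain both the initial and final reference
  settings.
* Inside LOSO evaluation, selection and search (when enabled) are re-run
  per fold on the training subjects only; an audit records the subjects
  seen by scaler fitting, selection and search and asserts the held-out
  subject is absent in every fold. For routine desk-scale runs they default
  off (fixed final hyper-parameters, all 46 features): the per-fold wrapper
  costs thousands of classifier fits, which is out of proportion for the
  synthetic study conditions, and the selection machinery is exercised
  separately on smaller matrices.

## Synthetic data

The generator emulates the protocol (NV → RH → AH per subject; default four
subjects with 280/680/2040 beats, i.e. ~10:1 hypovolemia imbalance and
AH:RH = 3:1) and the known effect directions: under hypovolemia PEP
lengthens (RH 1.15×, AH 1.30× the NV mean), heart rate rises (RR 0.90×/
0.85×), the BCG K and L amplitudes shrink (0.75×/0.60×, so the K-L
amplitude falls) and the K-L interval stretches (1.10×/1.20×); under AH
specifically LVET shortens (0.85×), raising PEP/LVET further, and PPG
amplitude falls (0.60×) versus the vasodilatory rise under RH (1.30×). HRV
state differences are deliberately mild (jitter 1.1× under hypovolemia) and
carry no AH-vs-RH signal, reflecting their equivocal physiology. Beat-level
noise: 2.5 ms fiducial latency jitter, 5% amplitude jitter, 8% relative
noise on windowed features; per-subject lognormal baseline offsets (8% on
amplitudes, 4% on timings — timing intervals vary less across subjects, and
this keeps fiducials inside their search windows) are removed by baseline
normalization.

Waveforms are Gaussian-lobe template trains (R spike plus P/T bumps; AO/AC
lobes; five alternating BCG lobes embedded in a gravity-tilted 10°
accelerometer frame; PPG dip-plus-pulse) with white noise and 0.2 Hz
baseline wander. They exercise extremum-based detection, zero-phase
filtering, rotation and gating, but they are *not* physiological
simulators: no motion artifacts, ectopy, morphology drift, sensor coupling
changes, or respiration. Passing tests therefore demonstrate correctness of
the pipeline's mechanics and its behaviour under the assumed effect
structure, not performance on experimental animal or human data. The PPG
trough/peak ground truth is read off the composed clean waveform because
the overlapping lobes shift the composite extremum slightly off the lobe
centers.

The direct feature-matrix path draws per-beat underlying parameters (RR,
PEP, LVET, latencies, amplitudes) from the same state-conditional
distributions and derives the 46 features from them, so internal identities
(ratio = PEP/LVET, wave-to-wave amplitude = amplitude difference) hold
exactly. A null configuration equalizes all state scales to provide the
no-signal control, whose LOSO accuracy collapses to the majority-class
prior (the cascade then labels every beat AH).

## Problem sizes and numerical notes

Desk-scale runs use the default 4-subject × 3000-beat feature matrices for
LOSO (≈40 s per evaluation), 2 subjects × 600 beats of rendered waveforms
for end-to-end effect recovery, and 170-beat noiseless recordings for
fiducial oracle comparisons — sizes chosen so the full suite and the
acceptance script each complete in minutes on one CPU while leaving
standard errors far below the tolerances tested. Determinism: every random
draw flows from `numpy` `SeedSequence([seed, subject, stream])`; refitting
with the same seed reproduces predictions bit-for-bit. Degenerate inputs
are handled explicitly: zero-variance features are clamped (warning) in the
scaler, undefined precision (no predicted positives) is reported as 0 with
a flag, absent truth classes are excluded from macro averages with a flag,
and zero-variance paired differences short-circuit the t-test (identical →
t = 0, p = 1).

## Known limitations

* The fiducial detectors are fixed-window extremum pickers; on real data
  with morphology variation they would need per-dataset window tuning (all
  windows are configurable) or template-based methods.
* The wrapper/search stack is expensive when enabled inside LOSO; budget
  parameters (`max_features`, `n_iter`, stopping tolerance) bound it.
* The stage-2 smoother runs over all beats including normovolemic spans;
  alternative gap-handling policies (smoothing only hypovolemia-classified
  runs) are not implemented.
* WFDB support is a minimal self-contained subset (format 32, text header,
  JSON annotation sidecar), sufficient for interchange of these recordings
  but not a general WFDB implementation.
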