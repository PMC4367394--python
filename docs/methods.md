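# Methods

## The monitoring problem and the two-phase model

A wearable node streams one ECG lead and tri-axial acceleration at 100 Hz
while the wearer goes about daily activities. Arrhythmia detection at this
sampling rate works from R-peak positions alone (no P/T delineation), so
any transient that mimics an ectopic beat — electrode motion at a posture
change, sustained artifact during jogging, a burst of transmission noise —
can raise a false alarm. The package separates *detection* from
*verification*: phase one attaches labels (beat type, segment signal
quality, segment activity) with k-NN classifiers; phase two is a small
expert system that suppresses an alarm whenever its context makes the
abnormal-beat label untrustworthy or physiologically implausible.

Assumptions worth stating: beats are classified independently given their
local context (beats i−2 … i+1); quality and activity are piecewise
constant over 5-s segments; heart-rate plausibility bands apply to
middle-aged adults (resting 60–100 bpm, exercise 60–160 bpm, endpoints
inclusive); and suppression uses any-fire semantics — the recorded rule id
follows the fixed priority R3 > R4 > R7 > R5 > R6 for bookkeeping only,
so the accept/suppress outcome is priority-independent.

## Signal conditioning

* Butterworth filtering, order 2, 5 Hz high-pass then 15 Hz low-pass,
  applied zero-phase (forward–backward) so detected R positions are not
  delayed relative to annotations; a causal mode exists for streaming
  emulation. The band-passed trace feeds *only* the QRS detector;
  morphology features read the normalised, unfiltered signal, because the
  band-pass distorts R amplitudes.
* Outlier-robust Z-score per whole recording (per axis for acceleration):
  samples more than 1.5 original SD from the median are excluded from the
  scale; the centre is the inlier mean, the scale the inlier population
  SD. Constant (zero-variance) recordings are rejected. The 1.5-SD rule is
  single-pass; heavy artifact bursts still leak some variance into the
  scale, which is the main residual source of cross-subject feature-scale
  spread (see Limitations).

## QRS detection

A slope-threshold detector suited to 100-Hz signals: slope is the
two-sample difference `S(t+1) − S(t−1)`; an onset is declared when a
single sample's slope exceeds `slope_threshold_fraction` (default 0.7) of
a running maximum slope. The R peak is the extremum of |amplitude| on the
normalised signal within `rpeak_search_s` (0.12 s) after onset; a
refractory period of 0.25 s follows. The running maximum is initialised
from the first 2 s and updated at each detection with weight 1/16, with
two robustness provisions, both config-exposed:

* **slew cap** (`maxslope_growth_cap`, default 1.2): one update can raise
  the running maximum by at most 20%, so a noise burst's huge slopes
  cannot ratchet the threshold far above true QRS slopes;
* **dropout decay** (`dropout_s`, default 2 s): if no onset is found for
  longer than the longest plausible RR interval, the running maximum is
  halved, so detection recovers promptly after an artifact episode.

Inverted-QRS support runs a second pass on the negated signal and keeps
the pass with the more regular RR series (coefficient of variation,
rounded to 2 decimals; ties broken toward the larger median |amplitude| at
the detected peaks, which prefers true R peaks over trailing edges and
makes the choice symmetric under global polarity flips).

## Features

* **Beat (13):** RR[i]; population variances of {RR[i], RR[i+1]} and
  {RR[i−1], RR[i], RR[i+1]}; mean amplitude between R[i−1] and R[i]
  (inclusive); |S(R[i−1]) − S(R[i])| and |S(R[i]) − S(R[i+1])|; means of
  amplitude in 0.12-s and 0.16-s windows centred at R[i]; means of
  gradient in 0.12/0.16/0.23-s windows; variance of gradient in a 0.06-s
  window; amplitude range in a 0.08-s window. A centred window of width
  w spans `2*round(w*fs/2) + 1` samples (odd count), truncated at record
  edges. "Gradient" is the same two-sample central difference as the
  detector slope. Population variance (÷n) is used throughout — the 2- and
  3-element RR variances make the n−1 convention unusable.
* **Quality (9):** 0.5-s windows shifted by 0.25 s (19 per 5-s segment),
  each summarised by mean/var/min/max of amplitude and mean/var of
  |amplitude|; segment aggregates are mean of means, mean of variances,
  variance of variances, least-squares slope of variance vs. window index,
  min of means, min of variances, range of variances, range of
  |amplitude| variances, and mean of |amplitude| means. Recordings are cut
  into consecutive non-overlapping 5-s segments (half-open
  [5k, 5(k+1)) s); a trailing remainder is discarded.
* **Activity (1):** deviation magnitude
  `sqrt(var(ax) + var(ay) + var(az))` over the 5-s segment — invariant to
  rigid sensor re-orientation because it is the trace of the axis
  covariance. An alternative (SD of the vector-magnitude signal) is
  provided as `vector_magnitude_sd`.
* **Calibration:** `calibrate_features` rescales a target population's
  features by the per-feature ratio of reference to target means, for
  cohorts that systematically move with different intensity (e.g. elderly
  vs. young subjects). It requires positive feature means and is not
  applied by default in the pipeline.

## Classification

`TieBreakKNN` is a scikit-learn-compatible estimator (fit/predict,
`get_params`); neighbour search is sklearn's `NearestNeighbors`, the vote
is local: majority of the k = 3 Euclidean neighbours; a tied vote goes to
the label of the nearer neighbour; a still-tied vote goes to the task's
negative (non-alarming) class — conservative alarm behaviour. Features
enter the distance as produced (the signals are already Z-scored); no
additional per-feature standardisation is applied by default. Beats
without full i−2 … i+1 context are marked unclassified, never alarm, and
are excluded from confusion matrices. MIT-BIH beat symbols map to
abnormal exactly on {V, E, !} (ventricular ectopy); all other beat codes,
including supraventricular ectopy, fusion and unknown/paced codes, map to
normal. Paced records 102/104/107/217 are rejected by default.

A zero metric denominator (e.g. sensitivity with no true positives) is
reported as N/A rather than 0 or 1. One published activity-classification
row prints sensitivity and specificity swapped relative to their defining
formulas applied to its own counts; this package always reports the
formula-true values and treats the row's accuracy (unaffected) as the
comparison point.

## Synthetic study conditions

The generator emulates a BSN session: a routine of ~20-s activity bouts
alternating static postures and dynamic activities (default 120 s, six
bouts; the evaluation cohorts use a 300-s, 15-bout routine). ECG beats are
sums of Gaussian lobes (P/Q/R/S/T); PVC-like beats are premature
(RR × 0.6), widened (× 2), taller (× 1.8), lack a P wave, carry a
discordant T wave and are followed by a × 1.4 compensatory pause. The
recording carries 0.25-Hz baseline wander, a 0.01-SD noise floor,
1.5-s motion-artifact windows at every bout boundary (amplitude 0.4 in
normalised units), and optional noise bursts (σ given per burst). The
accelerometer shows a per-bout gravity orientation plus 0.02-g sensor
noise; dynamic bouts add a 1–3 Hz oscillation of 0.3–0.8 g; bout
boundaries carry a 1.5-s spike of ~1 g.

Ground truth is recomputable from the scenario spec alone: a 5-s segment
is low quality iff it overlaps a noise burst; it is a transition iff it
overlaps a bout boundary (±0.75 s), otherwise static or dynamic by bout.
Cohorts draw per-subject parameters from named RNG streams of a master
seed: base heart rate ~ N(75, 6) clipped to 62–92 bpm, artifact scale
×U(0.8, 1.2), and roughly one 3–6-s noise burst per minute with
σ ∈ [1.5, 3.0] — artifact amplitudes of one-and-a-half to three times the
R amplitude, which is what severe motion artifact looks like on a wearable
lead.

What the generator does *not* model: physiological HRV spectra, P/T
morphology variation, arrhythmias beyond PVC-like ectopy, electrode
pop/saturation, and packet loss. Passing tests therefore demonstrate the
pipeline's mechanics and the rule layer's behaviour under controlled,
separable-by-construction conditions — not clinical performance on real
patients.

## Evaluation design and problem sizes

* Leave-one-subject-out (LOSO) segment classification runs on a
  10-subject cohort of 300-s sessions (600 segments); beat models train on
  a like-sized cohort with 8% ectopic beats (~3,700 classifiable beats).
* The injected-PVC check places one forced PVC per subject-varied session
  and counts the fraction of seeded runs in which it is labelled abnormal.
  Runs where the PVC falls inside a truly low-quality noise burst are
  excluded from the denominator: morphology there is unreadable by
  construction, and the framework's own design (rule R7) distrusts that
  signal rather than expecting the classifier to read it.
* The rule-layer check pools, over 10 master seeds, the false-alarm rate
  of all-normal cohorts before and after suppression and requires at
  least a two-fold reduction; on all-normal truth the post-suppression
  accuracy can be asserted to be exactly ≥ the pre-suppression accuracy,
  since every suppression converts a false positive into a true negative.

## Numerical and design choices

* Zero-phase filtering squares the Butterworth magnitude response; tests
  compare measured tone attenuation against the closed-form digital
  (bilinear-prewarped) magnitude.
* Slope endpoints (t = 0, n−1) are represented as zeros with a validity
  mask so windowing stays length-aligned.
* Sample indexing is 0-based; heart rate per segment is 60 / mean RR of
  the beats whose R peak lies in the segment, absent with < 2 beats;
  alarms in hr-absent segments are evaluated only against the hr-free
  rules R3/R4/R7.
* At a recording boundary a missing neighbour counts as static, so an
  isolated leading/trailing non-static segment becomes a transition —
  conservative (more suppression at the edges).
* R4's "immediately follows" window is exactly one segment.
* Each of R1–R7 can be disabled for ablation; with R1 off, non-static
  segments are all dynamic; with R2 off, all transitions.

## Known limitations

* The robust Z-score's single-pass outlier rule leaves burst-heavy
  recordings with a somewhat larger normalisation scale, so amplitude
  features transfer imperfectly across subjects with very different
  artifact loads; beat classification degrades accordingly in noisy
  sessions (the quality labels and rule layer, not the beat classifier,
  are the designed defence there).
* k-NN stores its training set; no condensation or metric learning is
  attempted.
* The rule layer's heart-rate bands are fixed population-level constants,
  not personalised.
* WFDB reading is import-guarded and untested against real MIT-BIH files
  in this environment; the record lists and paced-record exclusions are
  unit-tested as constants.
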