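# Methods

## Scope and data model

`naplab` analyzes cue-locked sleep EEG from targeted memory reactivation
(TMR) experiments: 8 scalp channels (F3/F4/C3/C4/P3/P4/O1/O2, 10-20
system) sampled at 200 Hz in microvolts, a 30-s-epoch hypnogram
(W/N1/N2/N3/REM), and cue events carrying condition (old-object,
old-scene, control), adjective id, and cueing round. Signals are
exchanged as EDF (16-bit) with TSV sidecars; epochs span [−1, 3) s around
cue onset (the sample at exactly +3 s is excluded; all other windows in
the package are closed intervals in seconds).

## Preprocessing

Artifact rejection is two automatic steps with sticky flags (a step can
add flags, never remove them):

1. *Amplitude/gradient criterion.* Per trial, the maximum absolute
   amplitude and the maximum absolute difference between adjacent samples
   are taken over all channels; trials outside median ± 3.5 IQR of either
   statistic are flagged. The per-trial maximum over channels (rather
   than per-channel criteria) was chosen because rejection is whole-epoch
   anyway; it is the stricter reading.
2. *Outlier screen.* On the surviving trials, per-trial variance and
   kurtosis (max over channels) are converted to robust z-scores
   (median/MAD, normal-consistent scale); z > 5 on either metric flags
   the trial. This automates what is usually an interactive summary
   review; the z cut-off is configurable.

ERP analyses high-pass filter at 0.5 Hz (zero-phase Butterworth, order 4
per pass) and subtract the −200–0 ms baseline mean. Degenerate inputs:
identical trials give IQR = 0 and flag nothing (the criterion requires
strict exceedance); a zero-MAD metric is skipped with a warning.

## Time-frequency analysis

Power is estimated by convolution with a 5-cycle Hanning-tapered complex
exponential per frequency (window 5/f s, e.g. 333 ms at 15 Hz; realized
as the nearest odd sample count, 67 samples at 200 Hz), from 4 to 30 Hz
in 0.5 Hz steps on the 5 ms sample grid. Time points whose window
exceeds the epoch are missing values, never zero-padded, so the
−300 to −100 ms baseline cannot absorb post-stimulus activity. Percent
change is computed after trial averaging: 100·(P − P̄base)/P̄base per
channel and frequency (the alternative, per-trial baselining, is a
one-line change but is not the default). Power is not log-transformed.

## Event detection

*Spindles.* Band-pass 13–16 Hz (fast; 10–13 Hz slow band available),
envelope = |analytic signal| smoothed with a 0.2 s moving average,
threshold = mean + 1.25 SD of the envelope over all eligible samples
(N2/N3, artifacts padded ±1 s excluded), events = supra-threshold runs of
0.5–3 s after merging runs separated by < 0.1 s. The envelope smoothing
departs from the raw analytic envelope and follows the convention of
most published spindle detectors: near threshold, beating between the
spindle carrier and in-band background noise otherwise fragments a
single physiological event into sub-criterion pieces. Both smoothing
length and merge gap are parameters.

*Slow oscillations.* Band-pass 0.5–2 Hz; successive positive-to-negative
zero crossings 0.8–2 s apart define candidates (fully eligible samples
only — candidates are excluded before threshold statistics are pooled);
candidates whose trough amplitude and trough-to-peak amplitude both
strictly exceed mean + 1.25 SD of the respective candidate-pool metric
are events. Strict exceedance uses a 10⁻⁹ relative tolerance so an
exactly degenerate pool (all candidates identical, SD = 0 up to float
noise) yields no events.

Both thresholds are *relative*: their operating point depends on the
data they are computed from. On featureless noise they flag the top tail
of the pool; as genuine events enter the pool they inflate the mean and
SD, raising the threshold (higher precision, lower sensitivity). The
detector-recovery calibration therefore measures sensitivity and
precision at moderate event density (spindle calibration: 3 SO/min and
2.5 spindles/min; SO calibration: 1.5 and 1.0 per min) on 20-min
recordings, with injected amplitudes at 3× the measured background level
(13–16 Hz envelope mean 2.30 µV; mean candidate trough 7.06 µV for the
0.5–2 Hz band — both measured once on event-free background and frozen),
on the unit-gain channels of the respective topography. Matching rules:
an injected event is recovered if a detection peak falls within ±0.5 s of
the spindle envelope maximum (±0.3 s of the SO trough); a detection is
correct if its peak falls inside any injected event's span. Under these
conditions both detectors exceed 0.94/0.94 (spindles) and 0.93/0.94
(SOs).

## SO-spindle coupling

For each eligible spindle (envelope maximum 1.5–2.5 s after an old-cue
onset, left-hemisphere channels F3/C3/P3/O1 by default), the continuous
recording is filtered once per channel in the SO band (0.5–2 Hz →
analytic-signal phase) and in the spindle band (13–16 Hz → analytic
envelope); a ±1.5 s segment (601 samples) of each series is cut around
the event peak. Filtering the continuous data rather than the 3-s
segment avoids band-edge artifacts at 0.5 Hz. The spindle envelope is
mean-removed within the segment before its Hilbert phase is taken —
without mean removal, the strictly positive envelope's DC term pins the
phase near zero and the anchor values below are unreachable.

The preferred phase is the circular mean over the 601 samples of the
circular distance (envelope phase − SO phase), with the cosine phase
convention on the SO. Anchors fixed by constructed-signal tests: an
envelope peaking at the SO trough reads 180°, at the up-state peak 0°,
and a quarter cycle *after* the up-state −90°. For a single transient
burst the estimator carries an intrinsic bias of up to ~15° at
quadrature phases (±90°), vanishing at the anchors (0°/180°); averaged
over events with von Mises phase jitter (κ = 4) the grand mean is
accurate to within ~5° at all phases. Subject-level statistics: circular
mean and resultant length R; Rayleigh test z = nR² with the standard
small-sample (Zar) p approximation; V test v = nR·cos(mean − ref) with
u = v·√(2/n) against the normal upper tail. R ≈ 0 marks the mean
direction undefined (warned, excluded from summaries).

## RSA

Feature vectors concatenate 8 channels × 41 samples (200 ms at 200 Hz,
ends included) at each center time, −0.2 to 2.5 s in 10 ms steps
(271 points), from 0.5 Hz high-pass filtered epochs; an optional < 4 Hz
low-pass tests whether the diagnostic information is low-frequency.
Spearman correlations (average ranks for ties) between all trial pairs
form the similarity matrix; the diagonal and lower triangle are dropped,
as are pairs sharing an adjective id (the same cue replayed in different
rounds). Within-category cells (object–object ∪ scene–scene) and
between-category cells are equated by sub-sampling the majority class
once per subject (the same cells at every time point); class means are
Fisher z-transformed with correlations clipped to ±(1 − 10⁻⁶).
Distinctiveness = 1 − mean raw between-category correlation over a
window (1.76–2.06 s for the behavioral correlation; 1.5–2.5 s for the
spindle-count correlation). Brain-behavior association uses Spearman
rank correlation across subjects.

## Cluster-based permutation inference

Paired-t maps across subjects (zero-variance cells get a ±∞ sentinel)
are thresholded at the two-sided α = 0.05 critical value by default;
supra-threshold points are connected per polarity (adjacent steps along
time/frequency; a declared neighbour list for the 8-channel montage:
F3–C3, C3–P3, P3–O1, F4–C4, C4–P4, P4–O2, F3–F4, C3–C4, P3–P4, O1–O2)
and summarized by mass (sum of member t-values). The null records the
maximum absolute cluster mass under random within-subject condition
exchanges (sign flips of the paired differences); p-values use the +1
correction. Under null data the family-wise false-positive rate
calibrates to 0.05 (±binomial error at 200 replicates).

## Behavioral scoring

"Recalled" means the associated image category was reported correctly;
items failing the separate object/scene categorisation check are
excluded. Retention(Tn→Tm) is the proportion of Tn-recalled items also
recalled at Tm; the TMR benefit is cued minus non-cued T2→T3 retention;
the discrimination index is the cued hit rate minus the non-cued
false-alarm rate in the post-study awareness test (T1-correct items
only, since only those were assigned to cueing conditions). Subjects
with an undefined retention (empty denominator) are excluded and
counted. Group summaries are condition means ± SEM; factorial inference
is out of scope.

## The synthetic generator

The generator produces the study conditions as defaults: 8 channels at
200 Hz, a 90-min recording with a staged hypnogram (brief W/N1 onset,
then N2/N3 cycling with one REM block per cycle), cueing at ISI
4 s ± 200 ms confined to N2/N3 (13 adjectives per old category and 13
controls, 5 rounds), and 50 encoded items per category with the ≥ 14
correctly-recalled inclusion criterion enforced.

Components, each driven by a named substream of the (seed, subject)
random state so stages can be regenerated independently:

* **Background**: Gaussian noise with 1/f power spectrum, 15 µV RMS per
  channel — matches the broadband spectral shape of sleep EEG without
  modeling sources. Channels are independent; real EEG is spatially
  correlated, so channel-covariance-sensitive conclusions should not be
  read off the synthetic data.
* **SOs**: Hann-windowed 5-cycle slow-wave trains (central period
  1.0–1.5 s, trough-then-peak, 75 µV, frontal-dominant gains). Only the
  full-amplitude central cycle is detectable (flanking cycles ~65% and
  < 10%). The train — rather than an isolated single cycle — is
  essential: the coupling estimator assumes the 0.5–2 Hz instantaneous
  phase is coherent across the ±1.5 s segment, which is true of real
  NREM sleep (slow activity is quasi-continuous) but not of a lone
  transient. With single-cycle events the estimator is biased by tens of
  degrees; with trains it recovers injected phases to within ~5°.
* **Coupled spindles**: flat-topped Tukey bursts (1.3× the host SO
  period, 20 µV, centro-parietal gains) with flanking bumps at 35%
  amplitude one SO period to each side, the envelope maximum placed
  where the host SO phase equals the configured coupling phase plus von
  Mises jitter (κ = 4 by default). The flat top keeps near-threshold
  events above the 0.5 s duration criterion; the flanking bumps give the
  spindle-band envelope the SO-periodic component that real coupled
  spindle activity shows and the envelope-phase extraction requires. A
  central burst longer than ~1.5 SO periods would invert the envelope's
  fundamental and is rejected by construction.
* **Cue-evoked responses**: every cue adds an evoked SO/k-complex train
  (80% amplitude, central trough 0.8–1.3 s post-cue — the latency range
  is a free simulation parameter, not an empirical claim), and with
  probability 0.25 (controls) × gain 2.0 (old cues) an extra coupled
  spindle whose envelope maximum falls 1.6–2.4 s post-cue, producing the
  condition-dependent spindle surge in the 1.5–2.5 s counting window.
* **Category patterns**: per subject, orthogonal unit channel-weight
  vectors for object and scene and category-specific slow (1.5 + 3 Hz,
  Hann-windowed) temporal profiles are added to every old-cue trial in
  the 1.7–2.3 s window, scaled by `category_pattern_snr` × background
  RMS × a lognormal subject factor (σ = 0.35, mean 1).
* **Behavior**: items recalled at T1 (P = 0.55) are split half/half into
  cued/non-cued within category; T2 retains 80% of T1-correct items; T3
  retains 50% of T2-correct non-cued items and 50% + benefit for cued
  items, where the subject's benefit is `behavior_effect` × the same
  lognormal factor that scales the subject's pattern SNR — linking
  distinctiveness and cueing benefit by construction. The baseline of
  0.5 keeps clipping of the cued probability negligible (P ≈ 0.3%); at
  0.6 the clipping visibly biased the recovered cohort effect.
  Discrimination responses are cue-independent (yes rate 0.3), matching
  the empirical finding that participants cannot identify replayed cues.

What the generator does not emulate: realistic sleep architecture
(stage sequence is deterministic), spatially correlated noise, muscle or
movement artifacts (the artifact-rejection tests use crafted epochs
instead), non-stationary spindle frequency, and any acoustic properties
of the cues. Passing recovery tests therefore demonstrate correctness of
the analysis code under the stated signal model, not performance on real
polysomnography.

## Test and calibration problem sizes

Recovery experiments run at desk scale: 20-min recordings for detector
calibration (four seeds, two detector-specific density settings),
25-min recordings × two seeds × three phases for coupling recovery
(~250 events per phase), eight 12-min subjects for the RSA cluster
localization (200 permutations), 200 replicate 2-channel × 50-point null
datasets (100 permutations each) for the family-wise error calibration,
and a 27-subject cohort at the real item counts for behavior. The
pipeline demonstration uses two 10-min subjects.

## Known limitations

* The preferred-phase estimator's single-event quadrature bias (~15°)
  is a property of the published procedure on transient bursts, not of
  this implementation; grand means over ≥ 100 jittered events are
  accurate to ~5°.
* The relative detection thresholds make sensitivity/precision depend on
  true event density; the calibration numbers above are specific to the
  stated densities and 3× amplitude.
* EDF output quantizes to 16 bits over an integer physical range; the
  write/read round trip is exact to within one quantization step but not
  bit-identical.
* With fewer than ~10 subjects the sign-flip permutation null is coarse
  (2ⁿ patterns); cluster p-values saturate accordingly.
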