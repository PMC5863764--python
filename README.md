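# naplab

Sleep-EEG analysis of targeted memory reactivation (TMR): during NREM
sleep, auditory cues associated with previously learned material are
replayed, and the question is whether and how the sleeping brain
re-processes the cued memories. `naplab` implements the full analysis
chain used to answer that question on 8-channel polysomnography —
cue-locked preprocessing, fast-spindle and slow-oscillation (SO)
detection, SO-spindle phase coupling with circular statistics,
sliding-window representational similarity analysis (RSA), cluster-based
permutation inference, and behavioral retention scoring — together with a
synthetic polysomnography generator that provides exact ground truth for
every stage.

## The analyses

**Event detection.** Spindles: the signal is band-pass filtered
(13–16 Hz fast band, two-pass 4th-order Butterworth), the amplitude
envelope is taken as |analytic signal| (smoothed 200 ms), and events are
supra-threshold runs of 0.5–3 s, with the threshold at mean + 1.25 SD of
the envelope over all artifact-free N2/N3 samples. SOs: the 0.5–2 Hz
filtered signal is searched for successive positive-to-negative zero
crossings 0.8–2 s apart; candidates whose trough amplitude and
trough-to-peak amplitude both exceed mean + 1.25 SD of the candidate pool
are kept.

**SO-spindle coupling.** For each spindle, a ±1.5 s segment (601 samples
at 200 Hz) around the envelope maximum yields two phase series: the
0.5–2 Hz instantaneous phase φ_SO (cosine convention: 0 = up-state peak,
±π = trough) and the Hilbert phase φ_env of the mean-removed spindle
envelope. The preferred phase is the circular mean over samples of
the circular distance φ_env − φ_SO: spindles peaking at the SO trough
read 180°, at the up-state peak 0°. Per-subject mean directions are
tested with the Rayleigh test (z = nR²) and the V test against an a
priori direction.

**RSA.** Every 10 ms from −0.2 to 2.5 s around cue onset, each trial is
summarized by its 8-channel × 41-sample raw-EEG window (328 features);
Spearman correlations between trials give within-category
(object–object, scene–scene) versus between-category similarity, with
same-cue pairs across cueing rounds excluded, cell counts equated by
random sub-sampling, and means Fisher z-transformed. Category
distinctiveness = 1 − between-category similarity in a stated window.

**Inference.** Paired-t maps across subjects are thresholded, connected
into clusters (fixed montage adjacency), and assessed against a
max-cluster-mass null from within-subject condition exchanges
(1000 permutations by default).

## Worked example

```
$ naplab pipeline --subjects 2 --duration 600 --seed 3 --n-perm 100 --out out/
subject 0: 111 clean trials, 518 spindles, 152 coupling events
subject 1: 113 clean trials, 563 spindles, 168 coupling events
RSA cluster test: 0 significant cluster(s)
mean TMR benefit 0.133
```

Two 10-minute synthetic subjects are simulated, epoched and cleaned
(111/113 trials survive artifact rejection), fast spindles are detected,
and the spindles whose envelope maximum falls 1.5–2.5 s after an old
memory cue enter the coupling analysis (152/168 events). With only two
subjects the RSA cluster test has no power (no significant cluster — the
paired-t permutation null needs more subjects), and the mean cued
minus non-cued retention difference (0.133) is a two-subject sample from
the generator's configured effect of 0.2. Per-subject tables
(`spindle_counts.csv`, `coupling.csv`, `rsa_sub-*.csv`, `behavior.csv`)
are written to `out/`.

The same stages are available individually (`naplab simulate`,
`preprocess`, `detect`, `tfr`, `couple`, `rsa`, `behavior`) and as
library functions (`naplab.events.detect_spindles`,
`naplab.coupling.couple_subject`, `naplab.rsa.within_between_series`, …).

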