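# Methods

This note documents the models, parameter choices and numerical decisions
behind `prososcreen`, and what the synthetic-data experiments do and do
not establish.

## Signal front end

Recordings are PCM WAV, mono or stereo, any rate ≥ 8 kHz. Stereo input
defaults to the left channel (the patient microphone in a two-headset
clinical setup); `mix` averages the channels. Integer PCM is scaled by
its full-scale constant; float input is peak-normalized only when it
exceeds ±1. No resampling is performed — every stage takes the sample
rate as a parameter. Frame and hop lengths are `floor(seconds · rate)`
samples, so at 44.1 kHz a 5 ms hop is exactly 220 samples; downstream
index arithmetic uses the realized frame spacing (220/44100 s), not the
nominal hop, which matters over minutes-long recordings.

## Pitch tracking

A RAPT-family tracker supplies per-frame F0 and the vocal-activity limits
used by boundary estimation:

* NCCF over lags spanning `f_min`–`f_max` (defaults 60–400 Hz, covering
  elderly male and female voices), correlation window 7.5 ms, computed on
  a ~8 kHz decimated copy of the signal (the F0 band needs no more; the
  energy envelope is *not* decimated). Lags are refined by parabolic
  interpolation.
* Up to 4 local NCCF maxima per frame enter a dynamic program with an
  explicit unvoiced state. Costs: `1 − nccf` for voiced candidates plus a
  small short-lag bias (0.05·lag/lag_max) that resolves period-multiple
  ambiguity in strongly periodic frames; `1 − 0.3` for the unvoiced state
  (so an isolated frame is voiced iff its best NCCF exceeds the 0.3
  voicing threshold); transitions cost 0.35 per octave of F0 jump and
  0.12 for voicing changes.
* Within each voiced run the track is 5-point median filtered; unvoiced
  frames carry NaN, never zero, so they cannot contaminate F0 statistics.

A silent signal yields an all-unvoiced track rather than an error.
Tracker accuracy on synthetic harmonic material is well inside 1 semitone
(ST); the test suite checks a 120→180 Hz glide frame-by-frame.

## Syllable-nucleus detection

The envelope is a 4th-order zero-phase Butterworth band-pass
(300–2500 Hz default — the vowel-energy band) followed by Hann-weighted
RMS over 10 ms windows at 5 ms hop and a 3-frame moving average. Peaks
are picked with a relative threshold `floor + r·(max − floor)` with
floor = 5th percentile and `r = 0.3`; candidate maxima closer than 60 ms
(faster than any plausible syllable rate) merge keeping the larger, and
peaks separated only by valleys shallower than the threshold margin merge
likewise, so every surviving peak is prominent by at least the margin on
both sides. The relative design makes detection invariant to amplitude
scaling, and raising `r` can only reduce the peak count.

Boundaries: each nucleus extends to the envelope valley bottoms toward
its neighboring peaks (ties toward the peak; shared bottoms split
adjacent nuclei; edge peaks clip to the signal extent), then the voiced
region containing — or, failing that, nearest to — the peak tightens both
edges to the vocal-activity limits. In practice the voicing limit is the
operative boundary at syllable edges while valley bottoms handle the rare
voicing gap. F0 statistics per nucleus exclude frames within 15 ms of a
boundary, whose correlation windows straddle the onset/offset transition
(short nuclei fall back to all voiced frames).

## The twelve features

Timing is measured on the nucleus timeline. Speech time SPT runs from
first nucleus onset to last offset, excluding leading/trailing silence. A
gap between consecutive nuclei counts as a pause iff strictly longer than
0.3 s. PPU and PPH are the pause-time and phonation-time *proportions* of
SPT in percent — so PPU + PPH = 100 exactly, and SPT = PHT + total pause
time; speech rate SPR = NSY/SPT and articulation rate ARR = NSY/PHT, so
ARR ≥ SPR always. "Syllable duration" (MSD) is nucleus duration.

F0 features default to Hz; a semitone mode (re 100 Hz, configurable) is
available. SDF and MFF are the SD (ddof = 1) and mean of per-nucleus mean
F0 — one value per syllable — while MVF is the max − min over all voiced
frames inside nuclei. With a single voiced nucleus SDF is 0; with no
voiced nucleus the F0 features are NaN and flagged.

## KS ranking and tiers

The two-sample KS statistic D is the sup distance between empirical CDFs
evaluated at every pooled point (ties handled by construction; internally
D is the exact integer `max|i·m − j·n|/(nm)`). The exact p-value counts
monotone lattice paths that stay strictly inside the band |i·m − j·n| <
c in integer arithmetic, equivalent to enumerating all C(n+m, n)
orderings; it is the default up to n + m = 30 — exact is the defensible
choice at the 10-per-group study size. Larger samples use the classical
Smirnov series `2·Σ(−1)^{k−1}exp(−2k²λ²)`, λ = D·√(nm/(n+m)), truncated
below 1e−12. Features are ranked ascending by p (ties break by canonical
feature order) and partitioned into SIG (p < 0.05), PSIG (0.05 ≤ p <
0.5) and NSIG (p ≥ 0.5); the 0.5 boundary goes to NSIG. No
multiple-testing correction is applied — the ranking is a screening
heuristic, not a confirmatory analysis.

## Classification

Leave-one-out cross-validation: each fold standardizes features with
training-fold statistics only, fits an SVM (linear kernel, C = 1,
configurable to RBF) and predicts the held-out subject; MD is the
positive class. Metrics come in two conventions: `standard`
(Sens = TP/(TP+FN), Spec = TN/(TN+FP), the default) and
`predictive_value` (PPV/NPV in the Sens/Spec slots), because screening
reports tabulate either. Results are deterministic for a fixed table and
configuration. The exhaustive search evaluates all 2^K − 1 non-empty
subsets (4095 for the 12 features) and reports the best subset per size,
preserving any non-monotonicity across sizes — more features need not
classify better, and the report must show that.

## Synthetic data: what it emulates

`synth_utterance` renders a syllable train: each syllable is a harmonic
source (amplitudes 1/h, i.e. −6 dB/octave tilt, capped at 4 kHz) with a
Hann amplitude envelope, a per-syllable F0 drawn log-normally around the
base (jitter in ST, truncated at ±2.5σ) and a linear within-syllable ST
glide; syllables are separated by short gaps or longer pauses, and white
noise is added at a configurable SNR (30 dB default). Ground truth —
onsets, offsets, per-syllable F0 and all twelve features — is computed
analytically from the generating timeline, never from the detector.

`synth_feature_cohort` draws each feature per subject from a truncated
normal with the published MD / non-MD mean, SD and range; 10 subjects per
group by default, matching the study size. Draws are independent across
features because no covariance structure is published — so experiments on
these tables exercise marginal separations, not feature interactions.

`synth_audio_cohort` derives per-group audio parameters from the same
published statistics: per-subject syllable count, pause count and mean F0
are truncated-normal draws from the NSY/NPU/MFF rows (the F0 base is
divided by the lognormal bias factor exp((σ_st·ln2/12)²/2) so extracted
MFF matches the table); per-syllable F0 jitter is set from the SDF/MFF
ratio (3.7 ST for MD, 3.3 ST for controls); syllable durations are
U(0.08, 0.18) s, short gaps U(0.05, 0.15) s and pauses U(0.6, 1.5) s,
which reproduce the published PHT/SPT/PPU/ARR scales. A `length_scale`
parameter shrinks syllable and pause counts proportionally without
touching rates or dispersions.

**What passing tests show — and don't.** On this material the detector
recovers syllable and pause counts exactly and F0 means to a fraction of
a semitone. Real read speech adds consonantal energy, coarticulation,
creak, clinician cross-talk and room noise, none of which the generator
models; exact-recovery results are a correctness check of the pipeline
logic and calibration, not a clinical performance claim.

## Problem sizes in tests and the acceptance script

Full-length cohort recordings (~300 syllables, 2–3 minutes at 44.1 kHz)
are exercised by a dedicated range-plausibility test. The repeated
end-to-end experiments (20-replicate direction check; the acceptance
script's audio study) run at `length_scale = 0.1` and 16 kHz — about
30 syllables and 15 s per recording — which preserves rates, proportions
and F0 dispersions while keeping many-replicate studies cheap; the
pipeline is sample-rate agnostic above 8 kHz. The end-to-end
discrimination check follows the pipeline's own workflow: rank features,
take the SIG tier (or the two top-ranked features when SIG is empty at
n = 10 per group) and classify that subset; classifying all 12 features
instead dilutes the discriminative ones, as the tier experiments show.
The published MSD row (printed to one decimal) is too coarse to validate
a duration convention and is excluded from range checks.

## Known limitations

* The nucleus detector's threshold constants (r = 0.3, 60 ms merge gap,
  envelope band) are calibrated on synthetic ground truth only.
* The KS exact p assumes a tie-free (continuous) null; tied data fall
  back to the same path-counting formula, which is then approximate.
* No diarization: clinician speech bleeding into the patient channel is
  not removed.
* The SVM's hyperparameters are not tuned (no nested CV); the linear
  kernel with C = 1 is the smallest-assumption default.
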