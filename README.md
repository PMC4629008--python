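# prososcreen

Transcript-free prosodic analysis of read speech for mild-dementia
screening.

Language decline is among the earliest measurable signs of dementia, but
most computational approaches need a manual transcript of the recording.
`prososcreen` implements a fully automatic alternative for clinicians and
speech researchers: it detects **syllable nuclei** directly from the
waveform, derives twelve prosodic timing and fundamental-frequency (F0)
features per recording, ranks the features by how well they separate a
mild-dementia (MD) group from controls, and evaluates the separation with
a leave-one-out SVM — including an exhaustive search over all feature
subsets.

## Method

**Syllable-nucleus detection.** The waveform is band-pass filtered to the
vowel-energy band (300–2500 Hz default) and a Hann-weighted RMS energy
envelope is computed at the full signal rate with a 10 ms window and 5 ms
hop (no downsampling, for fine temporal resolution). Nuclei are envelope
peaks above a relative threshold `floor + r·(max − floor)` (floor = 5th
envelope percentile, `r = 0.3`); peaks separated by valleys shallower than
that margin, or closer than 60 ms, merge. Nucleus boundaries are the
envelope valley bottoms toward the neighboring peaks, tightened by the
vocal-activity limits of a RAPT-style pitch tracker (normalized
cross-correlation candidates + dynamic-programming smoothing that
penalizes octave jumps and voicing transitions).

**The twelve features.** With nuclei at hand (an inter-nucleus gap
strictly over 0.3 s counts as a pause):

| | | |
|---|---|---|
| SPT speech time (s) | NPU number of pauses | PPU pause-time % |
| PHT phonation time (s) | PPH phonation % | SPR speech rate (syll/s) |
| ARR articulation rate (syll/s) | NSY syllable count | MSD mean nucleus duration (s) |
| SDF SD of per-syllable F0 | MVF max F0 range | MFF mean per-syllable F0 |

**Statistics and classification.** Each feature is compared between
groups with a two-sample Kolmogorov–Smirnov test (exact p by lattice-path
enumeration for small samples, Smirnov asymptotic series otherwise),
ranked by p-value, and binned into significance tiers (SIG p < 0.05,
PSIG p < 0.5, NSIG otherwise). Discrimination is measured by
leave-one-out cross-validated SVM (linear kernel, per-fold
standardization) reporting accuracy / sensitivity / specificity — under
the textbook convention or the predictive-value convention
(PPV/NPV), both of which appear in the screening literature.

Because no clinical recordings are public for this task, the package
ships a first-class synthetic-data module: read-speech-like syllable
trains with exact ground truth, and two-group feature cohorts drawn from
the published MD / non-MD descriptive statistics.

## Worked example

```python
from prososcreen import (UtteranceSpec, synth_utterance, extract_features,
                         synth_feature_cohort, rank_features, ranking_frame,
                         group_significance, loocv_evaluate)

# one synthetic read-speech utterance: 12 syllables, pauses after the 4th/8th
spec = UtteranceSpec(n_syllables=12, pause_positions=(3, 7), seed=7)
signal, truth = synth_utterance(spec)
vec, nuclei, track, env = extract_features(signal)
print(f"detected {len(nuclei)} nuclei (truth {truth.nsy}), "
      f"{vec.npu} pauses (truth {truth.npu})")

# a 10+10 cohort drawn from the published group statistics
table = synth_feature_cohort()
ranked = rank_features(table)
print(ranking_frame(ranked).head(4).to_string(index=False))
groups = group_significance(ranked)
feats = list(groups.SIG) or [r.name for r in ranked[:2]]
res = loocv_evaluate(table, feats)
print(f"LOOCV on {feats}: Accu {res.accuracy:.1f}  "
      f"Sens {res.sensitivity:.1f}  Spec {res.specificity:.1f}")
```

prints

```
detected 12 nuclei (truth 12), 2 pauses (truth 2)
feature   D        p  h  rank tier
    PPH 0.7 0.012341  1     1  SIG
    MFF 0.6 0.052448  0     2 PSIG
    ARR 0.5 0.167821  0     3 PSIG
    SDF 0.5 0.167821  0     4 PSIG
LOOCV on ['PPH']: Accu 65.0  Sens 90.0  Spec 40.0
```

The detector recovered every syllable and both pauses from the waveform
alone; on this cohort draw one feature separates the groups at p < 0.05
and carries 65% leave-one-out accuracy at n = 20 — the kind of
modest-sample result the method is designed to screen for.

The same workflow is available from the shell:

```sh
prososcreen synth --out-dir wavs --n-per-group 10 --seed 1
prososcreen extract wavs --labels wavs/labels.csv --out features.csv
prososcreen rank --features features.csv --out ranking.csv
prososcreen classify --features features.csv --mode search_all --out results.json
```

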