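# Methods

`speechscreen` implements an automated screening pipeline for cognitive
impairment (MCI and all-cause dementia) from brief Spanish verbal tasks:
four timestamped transcripts and their audio recordings per participant
are reduced to interpretable features, five binary classifiers (one per
task plus one acoustic) are selected by repeated cross-validated grid
search, and their scores are stacked into one screening score with a
sensitivity-prioritizing decision threshold.

## Inputs and tasks

Each participant contributes four tasks: semantic verbal fluency (SVF,
animal naming), alternating fluency (SVF-Alt, fruits and sports),
phonemic fluency (PVF, words starting with F) — each limited to one
minute — and an untimed picture description (PDT, the "Cookie Theft"
scene). Transcripts are word sequences with onset/offset seconds, as
produced by any word-level speech-to-text system; transcription itself is
out of scope. The target is binary: 0 cognitively normal (CN), 1 impaired
(either MCI + dementia, or MCI only, per the configured contrast).

## Verbal-task features

All lexicon lookups lowercase and NFC-normalize words, preserving accents.

**SVF.** Word count; repetition ratios (repeated-animal tokens / tokens,
and immediately-repeated tokens / tokens — two separate ratios because
total and consecutive repetitions carry different clinical signal);
semantic cluster count and mean size; switch rate; intrusion ratio;
temporal-cluster ("spurt") count and mean size; pause mean/SD. A semantic
cluster is a maximal run of ≥ 2 successively produced animals in which
every adjacent pair shares ≥ 1 subcategory; a switch is an adjacent animal
pair sharing none; non-animal words are removed before clustering (they
are scored separately), and cluster size counts words, not the
Troyer-style size−1. The subcategory taxonomy (pets / farm / wild / birds
/ fish-and-sea / insects, with a few dual members such as *gallina*) ships
as an editable CSV; no standard Spanish taxonomy exists, so this is a
documented stand-in. A spurt is a maximal run of ≥ 2 words with inter-word
gaps below `spurt_gap_s` (default 1.0 s; no published convention exists).

**SVF-Alt.** Fruit and sport counts, alternation violations (an in-list
word whose category repeats the previous in-list word's; the first in-list
word cannot violate), out-of-list intrusions, pauses.

**PVF.** F-word count, repeated-word count, and the consonant proportion
pooled over all F-word letters (vowels = a e i o u á é í ó ú ü), plus
pauses.

**PDT.** Unique-lemma count; verb/noun/pronoun/determiner/adjective rates
(counts / words); words in the first 30 s (onset strictly < 30 s); number
of distinct scene keywords detected (lemma match against a shipped
12-keyword list — also a stand-in, no published list exists); pauses.
Lemmatization and POS tagging use a pluggable lookup table (shipped for
the picture-description vocabulary); unknown words lemmatize to themselves
and fall in no POS bucket, so POS rates need not sum to 1.

**Pauses.** A silence is any inter-token gap ≥ `min_gap_s` (default
0.25 s), including the leading and trailing gaps; statistics are the mean
and *population* SD. Degenerate (empty) transcripts yield all-zero
feature vectors, so models never see non-finite values. A config switch
can instead derive the per-task pause statistics from audio energy (runs
of 25 ms frames with RMS below 2% of the peak frame RMS, edge-corrected by
one frame); token timestamps are the default source since they are
available whenever a transcript is.

## Acoustic features

Audio is resampled to 16 kHz mono, peak-normalized (removing session
volume differences), low-pass filtered with a zero-phase order-4
Butterworth at 7 kHz (cutoffs at or above Nyquist are rejected), and cut
into non-overlapping 25 ms frames (a 10 ms hop is available). Per frame:
12-bin chroma (equal-tempered pitch classes, A440), 13 MFCCs (26-filter
mel bank, log, orthonormal DCT-II), RMS, zero-crossing rate (crossings per
second, with frame-boundary crossings credited to the later frame so
contiguous framing loses none), spectral-flux onset envelope, spectral
centroid and bandwidth (magnitude-weighted mean and SD of frequency;
defined as 0 for empty spectra). Each is aggregated as mean and
population SD over frames; one tempo estimate (beats/min, onset-envelope
autocorrelation peak in 30–300 BPM) completes a fixed 61-value vector.
These are computed directly on numpy/scipy primitives. One vector is
extracted per task recording and the four are averaged into the
per-participant "speech" vector (how four recordings feed one acoustic
model is otherwise unspecified).

Note: the zero-phase (forward-backward) filter applies the Butterworth
magnitude twice, and the bilinear design warps frequency; the closed-form
gain of the implemented filter at frequency *f* is
`1 / (1 + (tan(πf/fs)/tan(πfc/fs))^(2·order))`, which the tests verify to
within 1%.

## Classifiers and ensemble

Five task models are trained independently on standardized features. For
the acoustic model only, univariate ANOVA-F selection keeps the best *k*
features with *k* ∈ {5, 10, 15, 20} as a searched hyperparameter;
zero-variance features get F = 0 and ties break toward the lower index.
Candidate families are logistic regression (C ∈ {0.01, 0.1, 1, 10}),
linear SVM (C ∈ {0.1, 1, 10}; scores calibrated to probabilities by
held-in-fold Platt sigmoid), k-NN (k ∈ {3, 5, 7, 11}), random forest
(100 trees, depth ∈ {3, ∞}) and gradient boosting (learning rate ∈
{0.05, 0.1}, 100 trees). The acoustic model searches the linear-SVM
family (its published final form); transcript models search all five.
The forest/boosting grids stop at 100 trees: a single-CPU repeated search
fits each candidate 100 times, and 300-tree fits triple that cost for no
measurable AUC gain at these sample sizes. All grids are constructor
arguments and can be pinned in config to reproduce any run.

Every candidate is scored by stratified 10-fold CV repeated 10 times
(AUC, accuracy, sensitivity, specificity and score MSE, reported as mean
and variance); standardization and feature selection are refit inside
each training fold. The winner maximizes mean AUC, with exact ties broken
by lower mean MSE and then by family order as listed — a deterministic
replacement for manual model choice. The winner is refit on all training
data. If the smallest class cannot fill 10 folds the fold count drops
with a warning.

The ensemble stacks the five scores: each participant's inputs are
*out-of-fold* scores (10-fold, each score from models not trained on that
participant) to avoid optimistic stacking; the scores are logit
transformed (`ln(p′/(1−p′))`, p clamped to [ε, 1−ε], ε = 10⁻⁶) and a
stacking classifier is chosen by the same repeated-CV search over all
five families.

**Threshold.** Final scores from stratified 10-fold CV are swept over
thresholds 0.00–1.00 in steps of 0.01 (decision rule: score ≥ t is
positive). Among thresholds whose mean sensitivity is at least the mean
specificity, the one maximizing Youden's J = sensitivity + specificity − 1
is chosen, smallest first on ties — a screening instrument prefers missing
fewer cases. The comparison is deliberately non-strict: on nearly
separable CV scores both rates equal 1 across the whole interior, and a
strict constraint would be satisfiable only at threshold 0 (everyone
called impaired, J = 0). If no threshold satisfies the constraint the
unconstrained J maximum is used with a warning.

## Evaluation

Confusion-matrix metrics (accuracy, sensitivity, specificity, precision,
F-score, Youden's J), Mann–Whitney ROC AUC (ties ½), score MSE, 101-row
threshold sweeps, and an MMSE benchmark (positive iff MMSE < cutoff,
cutoffs 24–28) for comparison against the standard bedside screen. The
MMSE-below-cutoff convention reproduces the published cutoff-27 operating
points exactly from the test-set group sizes. The 90/10 proportion
sometimes quoted for 10-fold CV is implemented as stratified 10-fold CV
(each fold ≈ 10%); a separate 70/30 stratified split utility with a
covariate-balance report prepares train/test sets, since the original
demographic balancing procedure is not described.

## Synthetic cohorts

No recordings are publicly deposited, so a generator produces labeled
cohorts end to end: demographics (age ≈ N(75, 8), education ≈ N(12.5, 5),
56% female, three centers), group MMSE (CN 28.58 ± 1.32, MCI
25.78 ± 3.17, dementia 23.33 ± 1.97), and four transcripts per
participant. Impairment is injected through interpretable shifts applied
to the MCI group and scaled ×1.8 for dementia (giving the monotone
CN < MCI < dementia ordering): fewer words per task, longer inter-word
gaps (lognormal, σ = 0.5·`noise_sd`), more repetitions and intrusions,
more semantic switches, more alternation violations, and poorer keyword
coverage. Presets: `null` (all zero), `moderate`, and `strong`
(6 words/min, +0.8 s pauses, +0.10 repetition, +0.22 switch, +0.18
violation, −0.30 coverage). Fluency gap means are derived from the drawn
word count so speech spans the one-minute window (independent gap and
count parameters would otherwise leave an unrealistic half-minute
trailing silence that dominates pause statistics); the group pause shift
is added on top, so slower groups also list fewer words before the cutoff
— as in real fluency testing.

Audio is synthesized as one 200–400 Hz sine burst per word at the word's
exact timestamps (5 ms cosine ramps) over digital silence. This makes
token- and energy-derived silence statistics agree by construction and
exercises framing, RMS, ZCR and silence detection deterministically, but
it is *not* speech-realistic: chroma/MFCC/centroid values are exercised,
not validated against speech, and passing tests say nothing about
acoustic-model performance on real voices. Default cohort composition
mirrors the study (87 CN / 63 MCI / 24 dementia); the reference runs in
`speechscreen.study` use 200 participants at the same proportions.

## Reference runs and their interpretation

`signal_recovery_run` (strong preset, n = 200, 70/30 split, full 10×10
search) demonstrates that the pipeline recovers injected group structure
(held-out AUC ≥ 0.9 expected); `null_control_run` (zero effects, train
n = 140, independent test n = 200) demonstrates the absence of leakage or
optimistic bias (held-out AUC ≈ 0.5; the 200-participant independent test
set keeps the chance-level AUC's Monte-Carlo SD near 0.04). These sizes
were chosen to exercise the full procedure at the study's scale while a
complete run (two cohorts, two full searches) stays in the tens of
minutes on one CPU. Because the cohorts are synthetic, these runs
validate the *machinery*, not clinical performance; the clinical operating
points are recomputed only as confusion-matrix arithmetic from the
published test-set composition.

## Numerical choices and edge cases

- Degenerate transcripts → zero vectors; all-zero audio passes through
  preprocessing unchanged with a warning; silent frames define RMS, ZCR,
  centroid and bandwidth as 0.
- A tiny DC bias (10⁻²⁰) is added before filtering to keep the IIR state
  out of the denormal-float range during long silences (orders-of-
  magnitude slowdown otherwise); it is below the resolution of a
  unit-peak signal.
- Score boundary: decision is positive at score = threshold exactly.
- One master integer seed drives cohort generation, splitting, fold
  assignment and all stochastic learners; identical seeds reproduce
  cohorts, CV reports and manifests bit-for-bit.
- Model artifacts are a JSON manifest (schema version, feature columns,
  chosen hyperparameters, threshold, seed) plus serialized estimators;
  scoring refuses artifacts with a different schema version.

## Known limitations

- The animal-subcategory taxonomy and picture keyword list are package
  stand-ins; clustering and keyword features shift under a different
  taxonomy.
- The lookup lemmatizer/POS tagger covers the shipped PDT vocabulary
  only; a real deployment should plug in a Spanish NLP tagger via the
  same lexicon interface.
- Tone-burst audio does not validate spectral features against speech.
- No covariate-adjusted prediction, no confidence intervals on AUC, no
  ASR error simulation.
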