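# Methods

This note documents the models, numerical choices and known limitations of
`melodecode`, in the order the pipeline runs.

## Stimulus representation

A melody is a monophonic, sorted, non-overlapping sequence of note events
(onset s, duration s, MIDI pitch) on a bar grid: 100 bpm, 4 beats per bar,
one bar every 2.4 s by default.  Time is continuous seconds internally;
sampling uses nearest-sample rounding for onsets and half-open intervals
`[onset, offset)` for gates, so boundaries are never counted twice.  Three
feature series are sampled at the analysis rate (64 Hz): the **envelope**
(per-note gate of amplitude 1 — all notes share the same loudness — with a
10 ms linear attack and a 0.5 s exponential decay, both configurable), the
**pitch series** (MIDI pitch held over the note, a configurable rest value
— default 0 — in silence; the value at rests is never read by the metrics),
and a binary **onset gate**.  The gate-plus-decay envelope is a stand-in for
an envelope extracted from rendered audio; users working with real audio
can substitute e.g. a Hilbert envelope, since all downstream code only
assumes a non-negative series at the analysis rate.

MIDI input is read by a purpose-built minimal Standard MIDI File codec
(format 0/1, running status, variable-length deltas, first set-tempo
honoured); CSV note lists (`onset_s,duration_s,pitch`) are equivalent.
Overlapping notes are rejected by default; a truncate-previous-note policy
is available.

## Synthetic cohorts

The simulator produces the structure the decoders assume — and nothing
more, which is what makes its tests sharp:

* **Melodies**: quarter/half-note rhythms filled bar by bar, pitches from a
  stepwise-biased random walk on the major scale.  A second generator
  produces a melody whose bars carry pairwise-distinct onset patterns (the
  8 beat-grid subsets containing the downbeat), used where unambiguous
  timing identification is required.
* **Forward model**: EEG = envelope convolved with a difference-of-gammas
  kernel (unit energy, peak ≈ 100 ms, confined to 0–350 ms lags) plus a
  mean-centred pitch contour low-passed below 1 Hz convolved with a second
  kernel, each routed into channels through fixed unit-norm random
  topographies, plus spatially mixed pink (1/f) noise.  The stimulus-driven
  part depends only on (subject, melody), so repetitions are identical up
  to noise.
* **SNR** is total stimulus-driven power over noise power, averaged across
  channels — one unambiguous, testable definition.  `snr_db=inf` disables
  noise.
* **shared_fraction** is a variance fraction: the drive mixes a source
  time-course common to all subjects (through subject-specific mixing) with
  subject-private kernels at amplitudes `sqrt(sf)` and `sqrt(1−sf)`.
* The relative strength of envelope- and pitch-driven signal in real EEG is
  unknown; both are exposed as gains (each branch normalised to unit RMS
  before its gain) rather than asserted as realistic.
* Channel layouts: the standard BioSemi 64 montage when 64 channels are
  simulated, otherwise a uniform spherical arrangement; an optional blink
  generator adds smoothed frontal deflections (off by default).

What the simulator does **not** emulate: volume conduction from realistic
sources, non-stationary artifacts, inter-trial attention drift, or any
nonlinear stimulus–response coupling.  Passing tests therefore demonstrate
correctness of the algorithms under their own assumptions, not performance
on recorded EEG.

## Preprocessing

Separate order-2 Butterworth high-pass and low-pass stages applied
forward-backward (`sosfiltfilt`): zero phase, squared single-pass magnitude.
Trials get 2 s reflection padding; shorter trials are rejected with the
minimum length named.  The 30 Hz low-pass doubles as the anti-alias filter
before polyphase resampling to 64 Hz.  Bad channels are detected per
session (concatenated trials) as variance > 3× the mean of the 6 nearest
spatial neighbours — "surrounding" read as spatial proximity — and replaced
by spherical-spline estimates (Legendre series, stiffness m = 4,
regularisation 1e-5, 50 terms); more than 25 % bad aborts with a
diagnostic.  Average reference last.  Per-trial interpolation is available
by calling the detector on single-trial sets.

## Joint decorrelation

Reliability components solve `C_bias v = λ C_total v` with `C_bias` the
covariance of per-stimulus trial averages, computed after whitening with
rank truncation (relative eigenvalue 1e-9 — average-referenced data is
rank-deficient).  Eigenvalues are trial-to-trial reliabilities in [0, 1];
components are reliability-ordered with signs fixed so the largest-
magnitude topography weight is positive.  Stimuli with one repetition enter
only the total covariance.

**Component selection.**  Whitened components all carry unit variance under
the total covariance, so "fraction of variance captured" is ill-defined on
raw variances (the spectrum is flat).  `component_variance` is therefore
each component's share of the *trial-averaged* (reliable) variance — the
normalised eigenvalue spectrum, which is non-increasing and sums to 1 — and
the default keeps the smallest leading set reaching 50 %.  On noiseless
data the reliability spectrum itself is flat and any partial cut is an
arbitrary rotation-dependent truncation; identity checks therefore retain
all components.

**Ocular rejection** is automated: a component is rejected when > 60 % of
its absolute forward-topography mass lies on frontal channels (unit-sphere
y > 0.6) *and* the frontal-vs-rest mean absolute weight z-score exceeds 3.
With no frontal channels in the layout nothing is rejected and a warning is
logged.

**Weighting vector**: per-component RMS over all trials of a subject and
condition, normalised to sum to 1 (zero-variance components get weight 0).
Because components are unit-variance-normalised on the fitting data, the
weights are near-uniform when computed on that same data; they depart from
uniformity when the model is applied to held-out sessions.  Normalisation
is inert for argmax classification.  JD is fitted per subject and per
condition; pooling conditions is a caller choice.

## MCCA

Per-dataset PCA whitening (rank-truncated at 1e-9) followed by PCA of the
concatenated whitened data; `Wᵢ` maps each subject into the joint space and
the summary matrix `Y = Σᵢ YᵢWᵢ` has mutually orthogonal columns ordered by
shared variance.  Trials must first be sorted into a common (condition,
melody, repetition) order; per-slot lengths are cropped to the common
minimum.  Exactly degenerate shared-variance eigenvalues (identical or
perfectly shared datasets) leave the basis arbitrary; tie groups are
rotated to sort by original-data variance (metric `Σᵢ W₀ᵀCᵢ²W₀`), keeping
results deterministic without touching non-degenerate spectra.  MCCA is
fitted per frequency band and per condition; `n_sc` defaults to the channel
count so the virtual subject has the dimensionality of a real one.

## Backward TRF (bTRF_env)

To predict the stimulus at time t the design matrix stacks EEG samples at
t+τ, τ ∈ [0, 350 ms] (23 lags at 64 Hz), zero-padded at trial edges.
Ridge regression with standardised columns and λ scaled by the mean
covariance diagonal; λ = 0 falls back to the pseudo-inverse, and by default
λ is selected by inner leave-one-trial-out reconstruction correlation on a
10^{−3..6} grid (a fixed λ is a config option — the pipeline default fixes
λ = 10 for speed).  Segment classification correlates the reconstructed
envelope with every distinct bar-aligned stimulus-envelope window (step 1)
at the given duration; ties break to the lowest candidate index and are
flagged; a zero-variance reconstruction scores 0 against everything.

## maxCorr

Segments are bar-aligned windows of the JD-component trials; 2.4 s × 64 Hz
is not an integer, so window boundaries round to the nearest sample
(consecutive step-1 windows then partition a trial exactly) and
correlations crop to the guaranteed common length (±1 sample).  The score
between two segments is the weighting-vector-weighted mean of per-component
Pearson correlations; zero-variance components contribute 0.  Test sets
tile trials with step = window length; the reference set uses step 1 and is
resampled without replacement to 96 segments when larger (the fixed
reference size keeps baselines comparable across durations; smaller pools
pass through unchanged).

**Leakage guard (on by default):** every segment cut from the test
segment's own trial is excluded from its reference set, not just the
identical segment — step-1 neighbours share raw samples and slowly varying
trial noise with the test segment and would otherwise match by identity
rather than by neural repetition.  A config flag restores the literal
all-other-segments reading; a regression test asserts the two differ on
noisy data.  Predictions are (melody, start-bar) pairs, so a match to a
different repetition of the correct stimulus counts as correct.  Exact
score ties break to the lexicographically smallest identity and are
flagged.

## Evaluation

Windows are quantised to a beat grid (0.6 s at 100 bpm; finer grids are a
config option) — the natural quantum of the stimuli, since the positions
metric needs a defined set of "possible note positions".  Note-onset
accuracy is the fraction of grid positions with matching note-vs-silence
labels.  Pitch decoding is the Spearman ρ of pitch values at positions
where both melodies have an onset; with fewer than 3 matched notes or
constant pitches the value is undefined and **excluded** from aggregates
(zero-filling would bias means), with the count reported as `n_undefined`.
Spearman is computed as Pearson on tie-averaged ranks (asserted equivalent
to the reference implementation in the tests).

The **pitch-shuffle baseline** permutes melody identities within classes of
reference segments sharing a grid-quantised onset pattern, then rescores.
Both decoders are blind to pitch labels — maxCorr compares EEG with EEG,
bTRF_env compares envelopes — so permuting labels before decoding is
mathematically identical to remapping the predicted identities afterwards,
which is how it is implemented (no re-decoding).  The mean over 100
shuffles is reported; singleton timing classes are fixed points, so with
all-unique timing the baseline equals the unshuffled score.  The **chance
level** is the 95th percentile of each metric under 100 permutations of
predicted identities across test segments; fewer than 20 shuffles triggers
a warning.

## Pipeline and reproducibility

`run_pipeline` composes simulation → preprocessing → JD → MCCA → decoding →
evaluation over a band × duration × decoder grid, writing melodies,
preprocessed trial sets (float32 on disk, float64 in computation), models,
per-segment records and an aggregated scores CSV stamped with a
configuration hash and the seed.  Every stage draws randomness from an RNG
derived from the master seed and the stage name, so a run is
bit-reproducible and stages are individually replayable; completed stages
leave manifests so an interrupted run can resume.  bTRF decoding runs on
sensor-space EEG and is skipped for the MCCA virtual subject, whose
"channels" are summary components.

## Benchmark problem sizes

The packaged experiments run desk-scale cohorts chosen to preserve the
statistical structure of the full design: 1–5 subjects, 2–4 melodies of
8–10 bars, 3 repetitions, 8–16 channels, 20 seeds for paired comparisons
and 10 for recovery checks.  The noiseless identity check pairs a
timing-unique melody with its exact transposition: timing then identifies
every window, and because Spearman ρ is rank-based, any residual tie
between the two melodies is inert for both metrics — with more than eight
one-bar windows the quarter/half rhythm alphabet forces timing collisions,
so this is the sharpest identity condition the geometry admits.

## Known limitations

* The envelope extraction of the original stimuli is unknown; the
  gate-plus-decay default is a documented stand-in.
* The automated ocular rejection replaces semi-supervised visual
  inspection; it targets topography only and will miss non-frontal
  artifacts.
* Group statistics (repeated-measures ANOVA, post-hoc tests) are left to
  standard statistics packages downstream; the package reports per-subject
  scores, baselines and permutation chance levels.
* Decoding unseen melodies absent from the reference set is out of scope.
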