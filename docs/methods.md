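# Methods

This note documents the models implemented in `miirkit`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Data model and preprocessing

A *trial* is one presentation of one music stimulus to one subject:
a channels × samples matrix with subject, condition, stimulus, and block
labels. The reference design is 9 subjects × 5 blocks × 12 stimuli
(perception condition), 64 BioSemi channels, recorded at 512 Hz and
processed at 64 Hz. Times are seconds, sample indices 0-based, windows
half-open `[start, end)`; a duration maps to `floor(seconds × rate)`
samples so a clip never reads past the stimulus end (the shortest
stimulus, 6.9 s, gives 441 samples at 64 Hz and 3532 at 512 Hz).

Preprocessing: zero-phase band-pass 0.5–30 Hz (Butterworth order 6,
forward–backward with `sosfiltfilt`; a zero-phase FIR sharp enough for a
0.5 Hz edge would be longer than the shortest trials), polyphase
downsampling with linear-edge padding, then per-channel normalization —
mean subtracted first, then scaled by the maximum absolute value, which
guarantees both zero mean and range [−1, 1] and is idempotent. Trials are
clipped to the shortest length only where a pipeline needs equal-length
inputs; note that clipping after normalization shifts per-channel means
slightly, which is accepted (re-normalization would alter the amplitude
relationship between trials).

## Similarity-constraint encoding

The encoder is a single spatial filter `w` (64 weights, no bias) with a
tanh output, trained on within-subject relative-similarity triplets with
dot-product similarity and hinge loss, mini-batches of 1000 triplets,
the Adam step rule, and 10 epochs with best-epoch selection on
validation-triplet error. Open parameters and their defaults:

- **Learning rate** 1e-3 (standard Adam default), configurable.
- **Margin** 1.0 by default (canonical hinge). Because the dot-product
  similarity scales with the trial length (~441 samples), a margin of 1
  is satisfied almost immediately and training effectively stops at the
  first feasible filter. For method-validation runs we therefore use a
  margin equal to the trial sample count, i.e., a unit margin on the
  *per-sample mean* similarity, which keeps the objective informative
  throughout training.
- **Weight decay** 0.0 by default, 30.0 in validation runs. This needs a
  note: with a purely adaptive per-coordinate step rule, the converged
  filter approaches a sign-like geometry (every coordinate the same
  magnitude), which preserves classification but discards the relative
  weight magnitudes — exactly the quantity a forward-model or unmixing
  comparison looks at. A small L2 penalty moves the stationary point to
  `w ∝ ∇(hinge)`, restoring magnitude information. We verified this
  directly: on noise-free single-source data the undecayed filter
  converges to `sign(m)` of the mixing column `m` (cosine ≈ 0.8 for a
  Gaussian-profile column), while a decayed filter reaches cosine > 0.99.
- **Initialization** uniform in ±0.01 under the run seed.
- **Tie-breaks**: equal similarity scores count as an incorrect triplet
  (conservative); at equal validation error the *later* epoch snapshot is
  kept (the longer-trained filter).
- **Epoch budget at reduced scale.** The number of Adam steps is
  triplets/batch × epochs; at the reduced validation scale (4 subjects,
  3 blocks → ~1.6k triplets per inner fold) 10 epochs give only ~20
  steps. Validation runs use 30 epochs to restore a usable step count;
  the full-scale design reaches ~500 steps within the standard 10.

Fold filters are polarity-normalized before averaging: the objective is
invariant to `w → −w`, so the sign is anchored on channel T7 (flip the
filter iff its T7 weight is negative; zero leaves it unchanged).

The forward model regresses each channel on the encoder output pooled
over all samples (`pattern_ch = cov(x_ch, y)/var(y)`), the standard way
to convert backward decoding weights into an interpretable generative
pattern.

## Cross-validation and triplets

Outer loop: leave one subject out (test set). Inner loop: hold out one
block of every training subject (validation set). Training triplets pair
every *ordered* same-class pair of a subject with every different-class
trial of that subject; ordering is required because the reference
position is asymmetric, and it is what reproduces the closed-form count
`Σ_subjects Σ_classes n_cls (n_cls − 1)(N − n_cls)`. Validation triplets
take the reference from the validation set and both partners from the
combined training + validation pool of the same subject. Triplet lists
are emitted in deterministic sorted order; shuffling happens at training
time under the run seed.

## Classifiers and statistics

The SVC is scikit-learn's `LinearSVC` (L2-regularized squared hinge,
`dual=False`), with C selected from a log grid 1e-3…1e3 by mean
inner-fold validation accuracy, ties toward the smaller C; the final
model per outer fold is refit on all non-test trials. The temporal
classifier learns one weight pattern per class on the encoded waveform
and trains with the Crammer–Singer multi-class hinge on the linear
scores; softmax is applied only for reporting activations (hinge on
softmax outputs is ill-conditioned, and prediction is unaffected).

The chance threshold is the smallest accuracy `100·k/n` whose exact
binomial CDF at the chance rate reaches `1 − α`. With n = 540, α = 0.001
this gives 12.22% (p₀ = 1/12), 39.63% (1/3), and 56.67% (1/2). McNemar's
test uses the mid-p variant `2·P(X ≥ max(b,c)) − P(X = max(b,c))`,
X ~ Binomial(b+c, ½), capped at 1, with the convention that zero
discordant pairs give p = 1.

## Tempo estimation

Bar-aligned epochs span 100 ms before to 2.4 s after a downbeat and are
accepted greedily in time order, rejecting any epoch that would overlap
the previously accepted one — overlapping epochs let a single data
segment appear at several epoch time points and can fabricate
autocorrelation peaks.

Autocorrelation scores are Pearson-style: the signal is centered and the
lagged product sum is divided by the overlap length and the signal
variance, so a periodic signal scores ~1 at its period and the estimate
is unbiased across lags. Two numerical choices:

- **Fractional lags.** A tempo `T` maps to lag `60·rate/T` samples,
  generally fractional; the score interpolates linearly between the
  neighboring integer lags. Rounding instead would alias neighboring
  grid tempi onto the same lag at 64 Hz (e.g., 62.5 and 63 BPM both round
  to lag 61) and make them indistinguishable.
- **Minimum overlap** of 6 samples (~94 ms): lags closer than that to the
  window length are dropped because their scores are estimated from a
  handful of products and are effectively noise. Six (rather than a more
  conservative guard) keeps the two-bar lag of a 25 BPM bar tempo
  scorable inside the 2.5 s window.

The tempo grid runs 24–300 BPM in 0.5 BPM steps. The lower end matches
the slowest bar tempo observable in the window; the 0.5 step keeps the
half-tempo harmonic of any integer tempo on the grid (with a 1 BPM grid,
half of 63 BPM would be unrepresentable and the harmonic-tolerant error
could never reach zero for such stimuli).

The aggregation heuristic interprets "pair of tempo values" as the
harmonic pair `(T, 2T)`: per row the pair maximizing the combined score
(ties → lowest index), element-wise lower-median across rows, then the
member with the higher column mean (ties → lower tempo). A grid with no
harmonic pair falls back to the maximal column mean. The tempo histogram
is the column sum over rows; histograms from several trials may be
averaged element-wise before peak-picking. The Fourier tempogram projects
mean-removed, Hann-weighted windows onto complex exponentials at `T/60`
Hz, normalized by the window length.

Note an intrinsic ambiguity: a perfectly periodic signal scores equally
at every integer multiple of its period, so a pure sinusoid's argmax may
land on an exact subharmonic; the harmonic-tolerant error metric
(`min over r ∈ {½, 1, 2} of |estimate − r·true|`) treats half and double
tempo as correct for this reason.

## Envelope reconstruction

The decoder maps lagged EEG (lags 0..`floor(0.375·64)` = 24 samples, EEG
*trailing* the stimulus — consistent with auditory response lags of
70–100 ms) to the stimulus envelope by centered ridge regression. The
plain least-squares fit is unstable on ~7 s trials, so the ridge penalty
defaults to the minimizer of the SVD-based generalized cross-validation
score over a log grid (1e-8…1e5); an explicit `ridge=0` on a
rank-deficient design raises an error advising a positive penalty.
Optional channel reduction projects the EEG onto the top principal
subspace of the training trial before fitting. Reconstruction uses the
"valid" convention (only fully covered samples; output length
`T − lags`), candidates are truncated — never zero-padded, which would
give away the shorter stimuli — and identification is the argmax Pearson
correlation, even when all correlations are negative. Leave-one-out
averaging combines per-trial decoders in channel space so decoders with
different subspace projections remain averageable.

## Synthetic data generator

The generator emulates the statistical structure the methods rely on —
not biophysics. Per trial, three unit-RMS sources are mixed through a
per-subject 64 × k forward matrix with unit-norm columns:

1. **Bar pattern** (amplitude 1.0): one bar of 8 Hz-low-passed noise,
   seeded by the stimulus id, tiled downbeat-to-downbeat with tapered
   edges. It is periodic at the bar tempo and unique per stimulus — the
   class-discriminative component, mirroring the bar-proportional
   periodicity seen in bar-aligned ERPs.
2. **Downbeat transient** (amplitude 0.5): a damped 4 Hz oscillation
   (120 ms decay) at every downbeat, with per-trial gain jitter
   (lognormal-like, σ ≈ 0.3) and latency jitter (±50 ms), modeling
   evoked-response variability.
3. **Envelope follower** (amplitude 0.5): the stimulus click-train
   envelope delayed by 100 ms, with per-trial gain jitter.

Stimulus envelopes are click trains at the nominal tempo with accented
downbeats and a per-beat accent profile seeded by the stimulus id — this
models loudness/articulation differences and keeps tempo-matched
stimulus pairs distinguishable by envelope. Background noise is pink
(1/f amplitude shaping), spatially white, scaled per trial so the
clean-to-noise power ratio equals the requested linear SNR (`snr=inf`
disables noise). Forward matrices are a shared base topography (broad
positive loading plus channel detail) perturbed per subject
(`subject_variability=0.2` by default). All randomness flows from the
config seed through `SeedSequence` spawning with fixed keys, so a given
seed reproduces the dataset bit-for-bit, independent of generation order.

**What the generator does not emulate:** volume conduction geometry,
spatially correlated or non-stationary noise, eye/muscle artifacts,
inter-subject latency differences, imagination conditions, or any real
spectral signature of auditory cortex. Passing the recovery studies
therefore shows the *algorithms* are correct and identifiable under
their own assumptions — it does not certify performance on real
recordings, where reported accuracies sit far closer to chance.

## Validation configurations

The recovery studies run at a reduced scale chosen to exercise the full
nested pipeline in seconds-to-minutes on one CPU:

- **Classification**: 4 subjects × 3 blocks × 12 stimuli, SNR 20,
  normalized trials; SCE hyper: margin = trial length, learning rate
  0.01, 30 epochs, weight decay 30. The SCE + SVC accuracy on held-out
  subjects is compared with the exact binomial threshold (1/12,
  p = 0.001).
- **Filter recovery**: same design but a single source with one mixing
  column shared by all subjects, and *no* per-channel normalization —
  max-abs normalization rescales channels by their signal content and
  provably rotates the least-squares unmixing vector away from the
  mixing column (we measured cos ≈ 0.76 normalized vs 0.99 raw), which
  would make the comparison test a property of the normalization rather
  than of the learner. The learned, fold-averaged filter is compared
  with the pooled least-squares regression of the known source on the
  observed data.
- **Tempo**: 50 single trials at SNR 20 over the eight stimuli whose bar
  tempo lies on the 0.5 BPM grid (63, 50, 40, 26, 35 BPM); stimuli with
  fractional bar tempi (e.g., 212/3 ≈ 70.67) are recoverable only to the
  nearest grid point and cannot give an exactly zero error by
  construction.
- **Envelope**: noise-free trials driven by the envelope source alone
  (amplitudes (0, 0, 1)); with the other stimulus-locked sources active,
  per-trial decoders partially absorb them and held-out correlations
  drop to ~0.96–0.99, so the isolated configuration is the correct
  noise-free identifiability check.

## Known limitations

- The SCE optimum under hinge loss is a feasible set, not a point; which
  filter is returned depends on the optimizer's implicit bias. The
  weight-decay variant documents and controls this, but magnitudes of
  the default (decay-free) filter should not be over-interpreted.
- The harmonic-pair tempo heuristic assumes the `(T, 2T)` reading of
  "pair of tempo values"; other readings (adjacent grid points,
  arbitrary pairs) are possible and would change behavior on signals
  without harmonic structure.
- `LinearSVC` with the default tolerance is deterministic for fixed
  inputs but not exactly reproducible across library versions.
- The Fourier tempogram of an impulse-like novelty curve has
  near-equal magnitude at the fundamental and its harmonics; histogram
  peaks may land on a harmonic, which the harmonic-tolerant error
  accepts.
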