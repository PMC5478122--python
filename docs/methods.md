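# Methods

## Signal model and feature extraction

A clip is a real matrix (channels × samples) at sampling rate *r*, of
duration *T* seconds (600 s in the contest layout).  Analysis windows of
`window_sec` (default 60) are taken every `step_sec` (default 30);
the window count is ⌊(T − window)/step⌋ + 1, so a ten-minute clip yields
19 windows.  Each window is multiplied by a symmetric Hamming taper,
zero-padded to the next power of two *N*, and Fourier transformed.  Bins
1..N/2 are retained: DC is excluded, the Nyquist bin kept, and bin *j*
(0-based) holds frequency (j+1)·r/N.  This convention reproduces the
contest feature counts exactly: 24,000 samples at 400 Hz → N = 32,768 →
16,384 bins per channel; 300,000 samples at 5000 Hz → N = 524,288 →
262,144 bins per channel.

Magnitudes (not powers, by default; `spectrum: power` is available) are
compressed with log1p.  The compression order is configurable:

- `log_order: pre` (default): log1p is applied to the bins *before*
  filtering.  Supervised weights are signed, so weighted sums of raw
  magnitudes can be negative, outside log1p's domain; compressing first
  avoids the issue entirely.
- `log_order: post`: filters act on raw magnitudes and log1p is applied to
  the filtered outputs after clamping to > −1 + 1e−12.

Both orders are legitimate pipeline designs; neither is asserted as "the"
reference behaviour.

Bands are half-open intervals [low, high), which makes the six canonical
bands disjoint at their shared endpoints (4, 8, 12, 30, 70 Hz).  Bands
above Nyquist truncate to empty and are dropped from the filter bank; a
configuration in which every band is empty is an error.  No detrending or
re-referencing is performed beyond the DC-bin exclusion.

## Filter estimation

Window-level samples are the estimation units: every analysis window of
every training clip contributes one feature vector of its clip's class
(class 0 = interictal = **Z**, class 1 = preictal = **Y**).  Filters are
fitted per subject, per channel and per band by default
(`scope=per_channel`); `scope=joint` fits one filter per band over the
concatenated channels, matching the channels×frequencies feature counts of
whole-vector filtering.  Which of the two the original contest runs used is
not established; both are provided.

The five objectives (DM, VAR, TVM, DS, SqD) are quadratic forms; except for
DM (closed form) the optimum is the algebraically largest eigenvector of a
symmetric moment matrix.  The matrices are never materialised: matvecs are
computed from the stored class sample matrices as X'(Xv)/n plus rank-one
mean corrections, O(nd) per product.  For SqD the paired expectation
E[(Z−Y)(Z−Y)'] is expanded under independent pairing by default
(`independent_moments`, deterministic); the streaming estimate over sampled
pairs (`sampled_pairs`) re-pairs every preictal window with a uniformly
drawn interictal window each sweep from a seeded generator, and converges
to the same operator in expectation.

Power iteration starts from the normalised all-ones vector and stops when
1 − |u⁽ᵏ⁾·u⁽ᵏ⁻¹⁾| < tol (default 1e−9, max 1000 iterations; the benchmark
harness relaxes this to 1e−6/150 since only the filter direction matters
there).  Raw power iteration converges to the largest-*magnitude*
eigenvalue; when that eigenvalue is negative the iteration is re-run on the
shifted operator M + |λ|I, whose dominant eigenpair is the algebraically
largest of M.  Eigenvector sign is fixed so the largest-magnitude component
is positive (ties to the lowest index).  A matvec that annihilates the
all-ones start vector raises a degenerate-operator error.

### A structural note on DS and VAR

On data whose class difference is a mean-power shift in a narrow sub-band,
the DS matrix E[ZZ']−E[YY'] contains the rank-two block m₀m₀' − m₁m₁'
(mₖ the class means).  Its eigenvectors mix the *overall mean-spectrum
direction* with the discriminative direction m₁−m₀, in proportions set by
‖m₀‖/‖m₁−m₀‖ — for log-compressed spectra the mean norm dominates, so the
DS eigenvector spreads roughly half (or more) of its squared mass along the
common mean shape rather than the discriminative bins.  The objectives that
cancel the common mean — DM, TVM and SqD — concentrate ≈ 0.87 of their
squared mass on the planted bins in the recovery study, while DS reaches
only ≈ 0.27.  This does not prevent DS from classifying well (its projection
still carries the discriminative component strongly, and DS attains the
largest benchmark AUC), but "weight mass on the right bins" is not a
property DS has on mean-shift effects.  Likewise VAR is blind to
multiplicative power effects under log compression (the variance of a
log-magnitude is scale-invariant); it responds to across-clip variance
differences, which is what the generator's variance-only effects exist to
exercise.

## Classification

Features are standardized with training-set mean and standard deviation
before any distance is computed (constant features get scale 1); the
posterior weight exp(−d²/2) is scale-sensitive and the contest pipeline's
scaling is unspecified, so this is an artifact decision, toggleable via
`standardize=False`.  Neighbour ties at the K-th distance break by stable
training-row order.  Weights are evaluated with a max-shift (the nearest
neighbour always has weight 1), so underflow cannot zero the denominator;
the all-underflow fallback returns the class-1 fraction among the K
neighbours.  K defaults to 40.

Clip aggregation is computed in log space as 1 − exp(mean(log1p(−pₜ)));
any window posterior of exactly 1 forces the clip probability to 1.  The
aggregate is permutation-invariant and bounded by the min and max window
posterior.

Leave-one-seizure-out cross-validation treats each one-hour preictal
sequence as one seizure: it is the validation unit of exactly one fold, and
interictal sequences are assigned to folds round-robin by ascending
sequence id.  Sequence membership is reconstructed from the manifest by
scanning segment indices in order and starting a new sequence whenever the
1..6 within-sequence counter fails to increase.

## Evaluation

AUC is the tie-corrected Mann–Whitney statistic (ties credit 1/2), computed
from average ranks; it equals the trapezoidal area under the empirical ROC
curve, and a property test asserts the equality to 1e−12.  DeLong's paired
test estimates the variance of an AUC difference from the empirical
covariance of placement values; p-values are two-sided by default
(one-sided available), identical score vectors return p = 1 by convention,
and a zero variance estimate with unequal AUCs is an error rather than an
infinite z.  No multiple-testing correction is applied.  Per-subject
reports add a pooled row computed on the concatenation of all subjects'
scores; a one-class subject has undefined AUC but its scores still pool.

## Synthetic data

Clips are synthesised by spectral shaping: for each channel a complex
Gaussian spectrum with E|X_k|² = n·r·PSD(f_k) is drawn and inverse
transformed, so the realised periodogram matches the target PSD in
expectation (verified to <10% relative error per band over 200 clips).
The baseline PSD is scale²·((1+f)^−α + floor) with α = 2, floor = 0.01 and
scale = 100 µV — a 1/f-type decay flattening into a noise floor, the
standard coarse description of iEEG background.  Planted effects multiply
the *preictal* PSD on an interval for a channel subset; variance-only
effects instead draw a mean-one log-normal per-clip factor, leaving mean
power unchanged while inflating across-clip variance.  Clips are organised
into six-clip one-hour sequences; the default configuration mirrors a
dog-like contest subject (16 channels, 400 Hz, 600 s clips, 26 interictal
vs 2 preictal sequences ≈ 93% interictal).

What the generator does *not* emulate: seizure morphology, non-stationarity
within a clip, inter-channel correlation beyond shared planted effects,
line noise and artifacts.  Passing tests therefore demonstrate the
estimators, solver and pipeline plumbing under controlled spectral truth —
not clinical forecasting performance on recorded iEEG.

### Study-scale configurations

Three named configurations fix the study conditions:

- `fast_scale_config`: 8 channels, 400 Hz, 2-minute clips (3 windows per
  clip at 60/30), 12 interictal + 4 preictal sequences.  Two-minute clips
  keep the full spectral resolution of the 60 s window while cutting
  simulation cost ~5×; this is the geometry used by the test suite and the
  acceptance runs.
- `recovery_config`: adds the recovery effect — preictal power ×4 on
  38–42 Hz of channels {0, 1} (≈ 327 of the 3277 low-γ bins).
- `narrowband_benchmark_config`: 8 preictal + 12 interictal sequences with
  a quarter-Hertz line at 40 Hz (≈ 20 bins), preictal power ×18, on 4 of 8
  channels.  The design is set by a signal-to-noise argument: the uniform
  low-γ average has per-window SNR ≈ Δ√k/(σ√m) (Δ the log-magnitude shift,
  k planted of m band bins, σ ≈ 0.64 the log-magnitude noise sd), which the
  narrow k keeps below reliable separability, while supervised estimation
  needs Δ√k ≳ σ√(m/n₁) with n₁ the preictal training windows — satisfied
  with ~70 of them.  The benchmark splits even-indexed sequences into
  training and odd-indexed into test (whole clips scored), so no window of
  a test sequence is ever seen in training.

## Numerical and degenerate-input choices

- FFT length: next power of two, zero-padded; windows shorter than 2
  samples rejected.
- Probabilities serialised with ≥ 6 significant digits; duplicate clip
  names in a prediction file are an error.
- MomentSet requires ≥ 2 samples per class; DM with identical class means
  raises a degenerate-operator error.
- KNN requires both classes present and K ≤ N.
- Aggregation of an empty posterior list is an error.
- All generator and pairing randomness flows through
  `numpy.random.default_rng` seeded explicitly; the CLI derives per-stage
  seeds from the global seed via `SeedSequence([seed, stage_id])`.

## Known limitations

- The per-channel filter scope and the KNN feature standardization are
  package design choices at points the original contest pipeline leaves
  unspecified; both are configurable rather than asserted.
- DeLong's test is asymptotic; at very small n with near-separable scores
  its variance estimate can vanish, which the implementation reports as an
  error rather than a spurious certainty.
- The reduced two-minute-clip geometry yields 3 windows per clip instead of
  19; aggregation behaviour at n = 19 is covered by unit tests on
  full-length clips, but the benchmark statistics are computed at the
  reduced scale.
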