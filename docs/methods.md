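# Methods

## Problem setting

Motor-imagery (MI) brain–computer interfaces discriminate imagined
left- vs right-hand movement from scalp EEG over the sensorimotor
cortex (electrodes C3, Cz, C4). The physiological signature is
event-related desynchronization (ERD): imagining a hand movement
attenuates the mu (8–13 Hz) and beta (14–28 Hz) rhythms over the
*contralateral* hemisphere. `stmi` implements a four-stage decoding
pipeline — time–frequency analysis, deep-feature extraction,
semi-supervised dimensionality reduction, and an optimized classifier
ensemble — together with a synthetic ERD generator so that every stage
is testable without access to recorded competition data.

## Synthetic ERD trials (`stmi.synthetic`)

Each 9-s trial at 128 or 250 Hz contains, on each of C3/Cz/C4, a mu
rhythm (10 Hz, amplitude 1 µV) and a beta rhythm (20 Hz, amplitude
0.5 µV) with independent uniform random phases, in additive power-law
noise (default exponent 1, i.e. pink). After the cue at t = 3 s the
channel contralateral to the label (C3 for right, C4 for left) has its
rhythm amplitude multiplied by

    1 − erd_depth · max(0, 1 − erd_decay · (t − cue)),

so the ERD is strongest at the cue and linearly recovers at
`erd_decay` per second (default 0.15/s). The recovery makes windows
late in the trial carry a weaker class signal, which is the feature the
sliding-window study is designed to expose. `snr` is the ratio of
baseline rhythm power, (1² + 0.5²)/2, to the noise power; `snr = inf`
disables the noise. Trials are pure functions of `(params, label)`;
datasets derive per-trial seeds from a master seed via
`SeedSequence([seed, i])` and interleave labels so any prefix is
balanced.

What the generator does *not* emulate: volume conduction between
channels, ocular/muscular artifacts, non-sinusoidal rhythm morphology,
inter-subject and inter-session variability, and ERS rebound. Passing
tests therefore demonstrate the pipeline's correctness and its
sensitivity to lateralized band-power effects — not expected accuracy
on recorded EEG.

## Discrete Stockwell transform (`stmi.stockwell`)

For the length-N sampled signal with 1/N-normalized DFT X, the
transform is evaluated literally as

    S[m, n/(NT)] = Σ_k X[(k+n) mod N] · exp(−2π²k²/n²) · exp(−2jπkm/N),

one FFT per voice n ≥ 1 (O(N² log N) overall). Numerical conventions:

* **Zero voice** — the Gaussian is undefined at n = 0; the standard
  convention S[m, 0] = mean(x) is used. The row is discarded by the
  7–30 Hz crop in the pipeline anyway.
* **Index wrap** — the shifted index k + n wraps modulo N; this is what
  makes the per-voice FFT identity exact, and it is verified against a
  literal triple-loop summation oracle in the tests.
* **Gaussian argument** — the window is evaluated at the literal
  k = 0..N−1 (not at wrapped/negative k). Consequence worth knowing:
  for a real tone at voice n₀, the conjugate-mirror voice N−n₀ carries
  slightly *more* mean magnitude than n₀ itself because its wider
  window also passes the n₀ peak; peak-voice assertions are therefore
  made on the one-sided range n ≤ N/2, which is also the physically
  meaningful half retained by `band_crop`.
* **Sign convention** — exp(−2jπkm/N) as printed; the magnitude map is
  identical under either sign.

The identity (1/N)Σ_m S[m,n] = X[n/(NT)] (the m-average annihilates
every k ≠ 0 term) holds to ~1e−16 and is asserted at 1e−10.

The pipeline applies an optional (default on) zero-phase 4th-order
Butterworth 7–30 Hz band-pass to the raw trial before windowing, crops
the magnitude map to 7–30 Hz inclusive, stacks C3 above C4, resizes
bilinearly to 220×220 and min–max normalizes to [0, 1]. 220 is chosen
so the two-layer CNN's flattened feature is 16·55·55 = 48,400-long. A
constant stacked map maps to the all-zero image (0/0 guard).

## CNN deep features (`stmi.cnn`)

Two (or three) blocks of [3×3 conv, same padding → batch norm → ReLU →
2×2 max pool] with 8, 16(, 32) filters, then flatten (channel-major)
and a 2-unit softmax head. Features are the flattened activations of
the last pooling layer in inference mode (batch norm uses running
statistics), giving 48,400 dims for the 2-layer net and 32·27·27 =
23,328 for the 3-layer net (floor division per pool). Training
regimen: cross-entropy, Adam (lr 1e−3), batch 16, 30 epochs by
default, He-initialized weights and zero biases, all seeded; with a
fixed BLAS thread count training is bit-reproducible. The network is
implemented directly on numpy (im2col + matmul convolutions) — small
enough that a deep-learning framework would add nothing but weight.

## Semi-supervised discriminant analysis (`stmi.sda`)

With between-class scatter S_b and total scatter S_t from the labeled
points, and the p-nearest-neighbor (default p = 5) 0/1 graph Laplacian
L = D − S over labeled *and* unlabeled points X, the projection solves

    S_b a = λ (S_t + β X L Xᵀ + ε I) a,

and keeps c = 2 directions. Numerical choices:

* **Span solver.** With d ≈ 48,400 and tens of samples, the d×d
  matrices are never formed; all quantities are assembled in an
  orthonormal basis of the span of the training points (rank ≤ N),
  which is exact because every direction with nonzero objective lies in
  that span. A dense solver exists for low-d cross-checks and the two
  agree to machine precision for d ≤ 50.
* **Ridge.** ε = 1e−6 · trace(S_t + βXLXᵀ)/rank, added to the
  denominator; singularity is otherwise unavoidable at d ≫ N.
* **Degenerate second direction.** For two classes rank(S_b) = 1, so
  the generalized eigenproblem has exactly one informative eigenpair;
  the λ ≈ 0 eigenspace is degenerate and any basis of it is an equally
  valid "second eigenvector". To make the model well-defined (and the
  two solvers identical), directions beyond the informative ones are
  completed deterministically as maximizers of total scatter subject to
  M-orthogonality to the already-chosen columns — i.e. the most
  informative variance directions within the null space of S_b.
* **Certificate.** Each fit stores the backward error
  ‖S_b a − λMa‖ / ((‖S_b‖ + |λ|‖M‖)‖a‖), asserted ≤ 1e−6; on
  informative pairs this implies the relative-residual form.
* **Sign convention.** Unit-norm columns with the largest-magnitude
  entry positive.

In the pipeline, 2/3 of the training trials are labeled; the remaining
third enters only through the graph term, and classifiers train on the
labeled projections. β defaults to 0.1 and can instead be selected from
a log grid by cross-validated linear-discriminant accuracy.

## Classifiers and fusion (`stmi.classify`)

Five base classifiers on the 2-D projections — SVM (kernel ∈ {linear,
quadratic, cubic, gaussian}, box constraint log-uniform 1e−3..1e3),
Gaussian discriminant (linear/quadratic/diag-linear/diag-quadratic,
implemented directly since the four covariance models have no single
sklearn equivalent), kNN (k ≤ 30; euclidean, Mahalanobis, Minkowski
p=3 "cubic", or cosine metric; equal/inverse/squared-inverse weights),
Gini decision tree (max split count searched), and a 100-tree random
forest (min leaf size, predictors per split). Hyperparameters maximize
5-fold stratified CV accuracy under sequential model-based search: 8
random starts, then a Matern-5/2 GP surrogate ranks 256 random
candidates by expected improvement (30 evaluations per classifier by
default; the discriminant's four types are grid-searched). Decision
fusion is strict majority vote over the five predictions; with five
binary voters a majority always exists, and an abstention fallback
prefers the first (SVM) vote so the operation is total.

## Metrics (`stmi.metrics`)

Accuracy, per-class sensitivity and precision in percent from the 2×2
confusion matrix; kappa = (Acc − 1/N_c)/(1 − 1/N_c) with Acc as a
fraction, hence kappa = 2·Acc − 1 for two classes. Row-normalized
percentage views support recomputation from published rate tables
(`ConfusionMatrix.from_rates`, equal class sizes assumed). Zero
denominators raise `UndefinedMetricError` rather than coercing to 0.

## Orchestration and problem sizes (`stmi.pipeline`)

Per window location: TFM images for all trials → CNN trained on the
labeled training trials → features for everyone → SDA fit → classifier
search on labeled projections → evaluation on the held-out 50 % of
trials (trial-level stratified split; windows of one trial never cross
the split). One independent stack per window location, since per-window
accuracies are the study's output. All stage seeds derive from the
config seed.

Default study conditions at desk scale: 80 trials (40/40 split, 27
labeled), 220×220 images, 30 CNN epochs, 15–30 search iterations. The
end-to-end checks run a single first post-cue window (3–6 s) for the
strong-ERD (depth 0.8, snr 1) and no-ERD controls, and a five-location
2-s-window sweep (starts 3..7 s, 1-s stride, 12 epochs, snr 0.15) for
the early-vs-late trend — at snr 1 every location saturates near 100 %
and no trend can express, while 0.15 is a realistic rhythm-to-
background ratio for scalp EEG. The pipeline default stride remains
250 ms.

## Known limitations

* The synthetic generator's simplicity means headline accuracies on it
  do not transfer to recorded competition data.
* The numpy CNN is CPU-bound; at the default sizes one window location
  trains in roughly a minute, so full 13-location sweeps at 250 ms
  stride are minutes-long studies.
* Bit-level determinism of CNN training assumes a fixed BLAS
  configuration; accuracies are robust across thread counts but losses
  can differ in the last ulps.
* The discriminant and SVM assume 2-D inputs from SDA; they work at any
  d but search spaces were chosen for the reduced space.
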