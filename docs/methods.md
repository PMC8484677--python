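# Methods

`hocorr` estimates timepoint-by-timepoint correlations — and, recursively,
correlations *between* correlation timecourses — in multivariate timeseries,
together with the simulation and evaluation machinery needed to know when such
estimates can be trusted. This note records the model, the conventions and
numerical choices the package commits to, and what the synthetic benchmarks do
and do not establish.

## Kernel-based instantaneous correlations

Given a T × K timeseries **X**, the instantaneous correlation at timepoint *t*
between columns *i* and *j* replaces the global column means of the Pearson
formula with kernel-weighted means

    μ̃_k(t) = Σ_τ κ_t(τ) X(τ, k),

where the kernel κ_t assigns each observed timepoint a weight describing its
relevance to time *t*. Five kernel families are provided — uniform, Dirac δ,
Gaussian (width parameter = variance σ²), Laplace (width = scale b), and
Mexican hat / Ricker wavelet (width = scale σ). Weights are evaluated on the
observed range τ ∈ [1..T] and renormalized per center so the weighted mean is
well defined at the edges: nonnegative families are normalized to sum to 1
exactly. The Ricker wavelet is the exception: its positive peak and negative
side lobes cancel almost exactly when summed over a symmetric window (the
truncated discrete sum is ~1e−16 for interior centers at practical widths), so
dividing by the raw sum would amplify the weights without bound. Mexican-hat
weights are therefore normalized by the sum of their absolute values, which
fixes the scale while preserving the center–surround contrast that motivates
the family.

Two estimator variants are exposed behind `mode`:

- **`as_printed`** (default): the kernel enters only through the mean; the
  cross-product and squared-deviation sums run unweighted over all τ. This
  variant is defined for *every* family, including an exact one-hot Dirac δ,
  which is essential because the δ kernel anchors both the recursion's
  blur-mitigation convention and the unstable-dynamics benchmarks.
- **`fully_weighted`**: the conventional weighted Pearson estimator, with the
  kernel inside every sum. It is a 0/0 for the exact δ kernel and can produce
  negative "variances" under the signed mexican-hat weights; both conditions
  raise informative errors rather than emit NaN.

Both variants reduce exactly (to machine precision) to the static Pearson
correlation under the uniform kernel, and with nonnegative weights every
estimate lies in [−1, 1] by Cauchy–Schwarz, with a unit diagonal at every
timepoint. A variance floor of 1e−12 guards the denominators; estimates are
errors, never NaNs, below it. Timepoints are 1-based at every interface.

Which variant the original formulation intends is genuinely ambiguous (the
printed estimator weights only the mean, which is unusual; the conventional
weighted-Pearson reading weights everything). Both are first-class and the
choice is recorded in output sidecars; the benchmarks in this package use
`as_printed` throughout.

## Dynamic inter-subject functional connectivity (DISFC)

For P participants observing the same stimulus, the stimulus-driven
correlation at time *t* is estimated by correlating each participant's
features against the leave-one-out average of the others, Fisher
z-transforming, averaging the symmetrized z-maps over participants, and
mapping back through the inverse transform:

    C̄(t) = M( R( (1/2P) Σ_p [ Z(Y^p(t))ᵀ + Z(Y^p(t)) ] ) ),

with Z(r) = ½·log((1+r)/(1−r)), R(z) = (e^{2z} − 1)/(e^{2z} + 1) = tanh(z),
and M the row-major upper-triangle-plus-diagonal vectorization. Correlations
are clipped to ±(1 − 1e−10) before Z everywhere, so exact ±1 never produces
infinities. The diagonal of Y^p is a cross-correlation with the leave-one-out
mean and is generally below 1; it passes through unmodified (no
re-unitization), since the averaging formula specifies none. The output is
symmetric by construction and invariant to participant ordering.

## Low-dimensional projection and the order recursion

A T × ((K²−K)/2+K) correlation stream is mapped back to T × K either by PCA
(one embedding fitted on the row-stacked streams of every participant in the
analysis set, so all groups share one space; component signs are fixed by
making each component's largest-magnitude loading positive) or by
per-timepoint eigenvector centrality. Correlations are signed but centrality
needs nonnegative weights; the default edge weight is |r| (Perron–Frobenius
then guarantees a nonnegative principal eigenvector), with a shifted
alternative (1+r)/2 behind a flag. Exactly tied dominant eigenvalues are
broken deterministically by projecting the all-ones vector onto the tied
eigenspace — the fixed point a power iteration started from **1** would reach.
Other graph measures can be plugged in through a registry (η: symmetric K×K
matrix → K-vector) but only eigenvector centrality ships implemented.

One recursion step maps order-n features to order-(n+1) features,
X_{n+1} = project(dyncorr(X_n)), so orders 0..n occupy exactly (n+1)·T·K
stored values — linear in n — instead of the O(T·K^(2^n)) the unprojected
correlations would need. Two stepping conventions exist:

- **decode mode** (`decode_mode=True`): orders 1..n−1 use a Dirac δ kernel
  and only the final step applies the analysis kernel, so temporal blur
  enters once regardless of the target order. PCA embeddings for the
  intermediate orders are fitted on the pooled δ-kernel streams and reused
  for every group in a run. The δ steps always use the `as_printed`
  estimator (the fully weighted variant is undefined for a one-hot kernel).
- **plain mode**: the analysis kernel at every step; each order blurs again.

The projection is lossy and the loss compounds with order; mapping X_n back
to the original feature space would need O(T·K^(2^n)) memory and is out of
scope.

## Synthetic data

First-order datasets draw s_t ~ N(0, Σ_t) independently across timepoints,
with the covariance timecourse following one of four regimes: *constant*
(one random Σ = CCᵀ, C i.i.d. standard normal), *random* (a fresh Σ_t every
timepoint), *ramping* (linear blend between two random anchors, with the
interpolation denominator generalized to T−1), and *event* (n_events random
covariances in consecutive equal blocks; T must divide evenly, default 5
events). Ground truth is stored as the correlation normalization
D^(−1/2) Σ_t D^(−1/2), since recovery is always scored against correlation
matrices. Default scales mirror the study conditions the benchmarks target:
K=50, T=300 for first-order simulations; K=10, T=300 for higher-order ones.

Higher-order datasets lift the order-1 correlation timecourse to order n by
per-timepoint Kronecker self-products m_{j+1} = m_j ⊗ m_j and sample
backward: a zero-mean draw from N(0, m_j) is reshaped to a square matrix
(row-major, matching the Kronecker index order), symmetrized by reflecting
the upper triangle onto the lower, PSD-repaired, and used as the covariance
of the next draw down; the order-1 draw is the observation. The repair —
eigenvalue clipping at 1e−10 followed by diagonal re-unitization — is a
choice the generating procedure leaves open, and it matters: any
PSD-ification is an even-function map whose expectation is spectrally aligned
with the draw's covariance, so the realized lower-order matrices carry a
measurable echo of their template (per-timepoint alignment ≈ 0.24 in our
simulations) even though the draws themselves are zero-mean. Generation
noise therefore propagates downward: observations reflect noisy versions of
the order-1 truth, while the top-order template enters exactly.

Multi-participant groups share one stimulus-driven signal timecourse s_t
(drawn through the full chain) observed through independent additive white
noise, x^p = s + noise_sd·ε^p. Truth matrices are correlation-normalized, so
signal features have unit variance and `noise_sd` is an SNR knob in signal
units; the default 1.0 (equal signal and noise power) is a deliberately
middling regime, and 0 gives identical participants. This shared-signal
construction is what makes the leave-one-out DISFC average meaningful: with
fully independent per-participant draws there would be no across-participant
covariance for it to isolate.

All generators are bit-reproducible from (spec, seed); replicate and fold
seeds are derived from a single run seed.

## Recovery benchmarks

Recovery at order n is the per-timepoint Pearson correlation between
estimated and true correlation entries. Scoring uses strictly-upper-triangle
entries only: the unit diagonals are constant in both vectors and would only
inflate the score, and the symmetrized generation makes mirror entries exact
duplicates. For n > 1 the benchmark runs the recursion *without* the
projection step — the strictly-upper entries of the order-(n−1) estimates
form the next timeseries, and explicit index bookkeeping maps every estimated
entry to its position in the Kronecker-structured truth. (A projected stream
lives in an arbitrary rotated K-dimensional space and cannot be compared
entry-wise with the truth; the exact route is exponential in order, which is
why the higher-order simulations use few features.) By default the benchmark
recursion also blurs only at the last step (δ kernels below the top order):
applying the analysis kernel at every step double-blurs the order-2 estimate
and, in our simulations, collapses constant-regime order-2 recovery from
≈0.63 to ≈0.18 while destroying it entirely for unstable dynamics.

Replicate summaries report the per-timepoint mean with a t-distribution 95%
confidence interval across datasets; the sweep driver scores the same
replicate datasets under every kernel so kernel contrasts are paired. Event
datasets can additionally be scored against each event's template and every
regime against the first/last timepoint's correlations, mirroring the
reference curves used alongside ground-truth comparisons. Edge dips at sharp
boundaries are finite-sample effects and are reported, not corrected.

What the benchmarks show, at the package's default problem sizes (20
replicates per regime for kernel comparisons; 10 for duration sweeps): wide
monotonic kernels recover slowly varying correlations best, with Laplace
width 20 the best compromise across regimes; an exact δ kernel wins when
every timepoint's correlations are independent; first-order recovery exceeds
second-order recovery for constant/ramping/event dynamics; and recovery
improves with series duration. One caveat deserves emphasis: in the random
regime, first- and second-order recovery are both near zero and their
ordering is *not* a robust property of the printed generation procedure — it
is controlled by the repair-induced template alignment described above, which
the procedure leaves unspecified. Our implementation yields first-order
recovery marginally above second-order there (statistically
indistinguishable at 20 replicates), the opposite ordering from the one
reported for the original simulations.

## Temporal decoding

Participants are split (seeded, sizes within ±1) into training and test
groups, the training group into nested halves. Order-0 group features are
the elementwise mean timeseries; order-n features are the group DISFC of the
members' order-(n−1) decode-mode streams, so the analysis kernel is applied
exactly once per feature order. For each order a timepoints × timepoints
matrix Λ_i correlates the two groups' feature rows; decoding combines
Λ = Σ φ_i Λ_i, labels each held-out timepoint by the argmax-correlated
template row (ties → lowest index, deterministic), and averages the
proportion correct over both group-role assignments. Chance is 1/T; relative
accuracy is accuracy − 1/T.

The weights φ live on the probability simplex. Raw accuracy is piecewise
constant in φ, so the optimizer maximizes a differentiable surrogate — the
softmax probability mass (temperature 0.1) on the correct timepoint,
averaged over timepoints and directions — over softmax-reparameterized
weights by L-BFGS from multiple starts (uniform, each vertex, and a fixed
battery of seeded Dirichlet points), then returns the candidate with the
highest *true* accuracy. Because the uniform point is always a candidate,
optimized training weights never decode worse than uniform ones.

A full run repeats this over 10 random group assignments (folds) and a bank
of analysis kernels (default {Gaussian, Laplace, Mexican hat} × widths
{5, 10, 20, 50}); summaries average over the bank first (a robustness
average over parameter choices, not a maximization) and report fold-level
means with t-interval CIs. Feature-set comparisons use paired two-tailed
t-tests across folds on the kernel-averaged accuracies — paired because the
fold assignment is shared across feature sets — both pairwise and against
the mean of the other sets, alongside the mean optimized weight per order in
the full decoder.

## What passing benchmarks do and do not show

The simulators produce independent Gaussian observations with exactly known
correlation structure: no temporal autocorrelation in the noise, no
hemodynamic-style smoothing, no non-Gaussian tails, no participant
heterogeneity beyond i.i.d. white noise. Recovery and decoding results on
them validate the estimators' algebra and their qualitative kernel/order
trade-offs, not performance on real recordings, where kernel widths interact
with intrinsic autocorrelation and the stimulus-driven fraction of variance
is far smaller. The decoding benchmark's shared-signal SNR (noise_sd = 1) is
far more generous than typical neuroimaging data.

## Known limitations

- The inverse-transform step of DISFC does not commute with averaging, so
  C̄ is a quasi-correlation: entries are bounded by 1 but the matrix is not
  guaranteed PSD.
- `fully_weighted` mode is unavailable for the δ kernel and unreliable under
  mexican-hat weights; mexican hat is intended for `as_printed`.
- The exact recovery recursion is memory-exponential in order (it exists to
  validate the scalable projected path, not to replace it) and refuses to
  correlate more than 256 columns by default.
- Random-regime higher-order recovery orderings depend on the PSD-repair
  convention (see above) and should not be treated as a stable property.
- Eigenvector-centrality projections discard activity information by design;
  only PCA supports (approximate) inversion back to correlation space.
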