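# Methods

## Model and procedure

The classifier treats prediction as lossy compression.  Let C be the true
class (N targets), X the vector of per-feature bin indices, and P the
predicted class.  Training chooses an encoder q(p|x) minimising the
generalized information-bottleneck objective

    L(q) = H(P) − α·H(P|X) − β·I(P;C),        α ∈ [0, 1], β > 0,

subject to the Markov chain C → X → P.  α = 1 recovers the original
bottleneck objective I(P;X) − β·I(P;C); α = 0 is the deterministic
bottleneck, whose optimum is a hard function X → P and therefore directly a
classification rule.  β weighs preserved class information against
representational cost; because the reported performance measure is itself
I(P;C) per unit time, maximising I(P;C) through the bottleneck optimises
the interface's figure of merit rather than a surrogate such as accuracy.

The solver iterates the self-consistent updates: score every (x, p) pair by

    ℓ(x, p) = log₂ q(p) − β·KL( p(c|x) ‖ q(c|p) )   [bits],

set the encoder row to softmax(ℓ/α) for α > 0, or to the argmax of ℓ for
α = 0 (ties to the lowest cluster index), then recompute the cluster
marginal q(p) and decoder q(c|p).  Each restart begins from a seeded random
initialisation (Dirichlet(1) rows for α > 0, a random hard assignment for
α = 0) and runs until |ΔL| < 1e-8 bits or 1000 iterations; the best of
`restarts` (default 20) solutions by objective is kept.  The objective
sequence is recorded and is non-increasing within each restart.  Empty
clusters and zero decoder entries are handled by clamping log arguments at
1e-300, which makes them effectively unselectable without special-casing
infinities.

Because local optima are real (the attained objective varies across
restarts on noisy joints), correctness of the α = 0 path is checked against
an exhaustive oracle that enumerates every deterministic map from the
retained x values to clusters (guarded to ≤ 12 support points and ≤ 3
clusters) and returns the global minimiser.  On random 3-class joints with
|X| ≤ 10 the 50-restart solver attains the enumerated optimum in ≈ 99–100
of 100 instances.

## Discretisation

Each feature receives equal-width bins spanning its training min/max.  The
bin count is the per-class estimator output averaged over classes and
rounded to the nearest integer, halves up.  Two estimators are provided:
Freedman–Diaconis, interpreted as the standard width rule
2·IQR·n^(−1/3) with count = ⌈range/width⌉ (zero range falls back to one
bin; zero IQR to Sturges), and Sturges, ⌈log₂ n⌉ + 1.  Bins are half-open
[l, h) with the last bin closed; at prediction time out-of-range values
clamp to the edge bins rather than being rejected, consistent with the
skew-normal model whose edge bins absorb the open tails.

Bin probabilities P(Bᵢ = b | Cₖ) come either from per-class counts (no
smoothing — impossible cells stay at zero and are handled by support
filtering) or from a maximum-likelihood skew-normal fit per (feature,
class), with interior bins as CDF differences and the extreme bins taking
F(h₁) and 1 − F(l_last) so each row sums to one exactly.  A fit that does
not converge falls back to a normal fit (shape 0) and logs a warning.  The
skew-normal route acts as a smoother: on large samples the two models agree
to within a few percent per bin, but the parametric version is markedly
less noisy at realistic training sizes.

## Joint model and support filtering

The bin vector X is flattened by a row-major mixed-radix code (first
feature most significant).  Under conditional independence given the class,
p(x, c) = p(c)·∏ᵢ P(Bᵢ = bᵢ|Cₖ); the class prior defaults to empirical
training frequencies (uniform for balanced designs) with an explicit
uniform override.  The full grid is dense and capped at 10⁶ cells with a
clear error — the state space grows exponentially with the number of
classes, which is the method's practical limit.  Rows with marginal
p(x) < pmin (default 1e-12) are dropped from the support; a test sample
landing on a dropped cell is left unclassified.

## Classification rules and the reject option

Clusters of P are arbitrary labels, so after solving, every injective map
from occupied clusters to classes is scored by training accuracy and the
best (ties: lexicographically smallest) is kept.  Solutions occupying fewer
than N clusters are accepted as-is; the unmatched classes are then simply
never predicted.

Classifier 1 outputs the mapped class of the sample's bin vector when the
encoder row puts mass ≥ 1 − τ on one cluster (τ default 1e-6; α = 0 rows
satisfy this exactly, α = 1 rows in practice are numerically one-hot on
separable data), otherwise abstains.  The pure argmax variant is available
behind a flag.

Classifier 2 votes over the (2n+1)^F offset neighbourhood of the sample's
bin vector: each neighbouring cell classified as class i contributes one
vote; offsets leaving the grid or landing on filtered/rejected cells count
for no class.  A class is predicted when its vote count reaches the
threshold t.  Valid thresholds satisfy (2n+1)^F/2 < t ≤ (2n+1)^F; the lower
bound guarantees at most one class can reach t (votes for distinct classes
are disjoint over the same ≤ (2n+1)^F cells).  The vote condition is
"count ≥ t": the top of the range then means *all* neighbouring cells must
agree, and n = 0, t = 1 reduces exactly to Classifier 1.  A t below the
majority bound may produce ties and raises an explicit ambiguity error.

## Performance measures

Confusion tables carry an extra reject column.  Accuracy is per classified
sample.  Mean detection time is MDT = w + (1/P(classified) − 1)·s + gaze,
where w is the window length (default 1 s), s the sliding step (default
0.125 s) and gaze an optional gaze-shift constant (0.5 s is typical when
modelling overt attention switching); abstaining therefore costs time, not
errors, and P(classified) = 0 yields an infinite MDT and zero ITRs.
I(P;C) is the plug-in mutual information of the classified-sample joint
(reject column excluded and renormalised; an (N+1)-outcome variant that
keeps the reject column is available behind a flag).  ITR_mi =
I(P;C)·60/MDT; the Wolpaw ITR uses the doubly-symmetric-channel closed form
log₂N + a·log₂a + (1−a)·log₂((1−a)/(N−1)) instead.  On a doubly symmetric
confusion table with uniform classes the two coincide exactly, which the
tests assert to 1e-12.  The plug-in estimate is deliberately uncorrected
for bias — it is what the confusion matrix directly supports — so small
classified counts overstate I(P;C) by roughly (N−1)²/(2·n·ln 2) bits.

## Synthetic data: what it does and does not emulate

The feature generator draws one real-valued feature per class from
skew-normal distributions that are conditionally independent given the
class, with the attended class's feature location raised by δ (in scale
units).  Defaults: 3 classes, location 0, scale 1, shape 3, δ = 2, and 560
samples per class over 5 trials — 112 windows per trial, matching a 15 s
stimulation trial scanned by a 1 s window every 0.125 s.  δ = 10 gives an
essentially separable problem (cross-validated accuracy ≥ 0.99); δ = 0
carries no class signal (cross-validated I(P;C) ≈ 0); δ ≈ 1.5 gives the
moderately noisy regime in which the vote-threshold scan shows its
characteristic rise-then-drop.  A `boost_map` can attach the elevation to a
non-matching feature, exercising the fact that the method never assumes
"largest feature = correct class".

What the generator does **not** emulate: temporal autocorrelation between
overlapping windows within a trial (samples are i.i.d. given the class),
cross-feature dependence (real PSDA/CCA features of the same window are
correlated), non-stationarity across trials, and artefacts.  Passing tests
therefore demonstrate correctness of the machinery and its behaviour under
the model's own assumptions — not performance on real recordings, where
within-trial dependence in particular inflates apparent training-set sizes.
Trial-wise (leave-one-trial-out) cross-validation is used everywhere for
exactly that reason.

The EEG generator emits sinusoids at a target frequency's first harmonics
(geometrically decaying amplitudes, shared random phases) plus seeded,
unit-variance 1/f noise per channel; it exercises the PSDA/CCA front end
and the end-to-end pipeline, not physiological realism.

## Feature extraction front end

A deliberately minimal implementation of the classical pipeline:
re-reference (subtract a reference channel, e.g. Cz, from occipital
channels), 1 s sliding windows every 0.125 s, periodogram powers at the
first three harmonics of each candidate frequency plus their sum
(rectangular window, 'spectrum' scaling, nearest-bin lookup, averaged over
channels), and the largest canonical correlation against sine/cosine
references at those harmonics.  Canonical correlation is computed as the
top singular value of QxᵀQy over SVD-derived orthonormal bases; near-null
directions are dropped so duplicated channels cannot contribute
numerical-noise correlations.  Per-target blocks are reduced to one feature
per class by one-vs-rest LDA (lsqr solver with automatic shrinkage, which
also covers singular scatter matrices), taking the signed distance to each
class's decision border.  Filter-bank and task-related component analysis
are out of scope.

## Numerical choices and degenerate inputs

- All logarithms base 2; all information quantities in bits; 0·log 0 = 0.
- Probability validation: distributions must sum to 1 within 1e-12
  (joints within 1e-9); tiny negative plug-in MI values clamp to 0.
- Argmax ties everywhere resolve to the lowest index for determinism.
- Rounding "to the nearest integer" uses halves-up; quantiles use linear
  interpolation.
- Constant features get a single bin; constant windows are rejected by the
  CCA with a clear error.
- All stochastic components (solver restarts, generators) are driven by
  explicit integer seeds; repeated runs are bitwise identical.

## Known limitations

- Dense enumeration of the bin grid limits the method to few classes
  (≈ 5 with typical bin counts) — inherent to the exact bottleneck, not to
  this implementation.
- The conditional-independence joint is a modelling assumption; strongly
  dependent features will mis-calibrate p(x, c) even when each marginal fits
  well.
- The iterative solver guarantees only a local optimum; the restart count
  trades runtime for the probability of hitting the global one (the
  exhaustive oracle bounds this empirically on small instances).
- No multiple-subject orchestration, no online adaptation, no posterior
  calibration.
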