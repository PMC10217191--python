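# Methods

## Model and guarantee

All mechanisms in this package privatize empirical risk minimization for two
models on N samples (x_n, y_n), x_n ∈ R^D:

* linear regression, cost (1/N) Σ (y_n − x_nᵀw)², with y_n ∈ [−1, 1];
* logistic regression, cost (1/N) Σ [log(1+exp(x_nᵀw)) − y_n x_nᵀw],
  with y_n ∈ {0, 1}.

Both are represented as a quadratic f_D(w) = β + αᵀw + wᵀM w.  For linear
regression this is an exact algebraic rewrite (β = (1/N)Σy², α = −(2/N)Σyx,
M = (1/N)Σxxᵀ).  For logistic regression it is the second-order Taylor
surrogate of log(1+exp z) at z = 0 with constants log 2, 1/2, 1/4
(β = log 2, α = (1/N)Σ(1/2−y)x, M = (1/(8N))Σxxᵀ).  The surrogate is what
gets minimized everywhere in this package, including the "non-private"
reference — its classification decisions coincide with the exact logistic
fit's for all practical purposes at the signal levels considered, but it is
a surrogate, and the package makes no claim about the exact-likelihood
optimum.

Privacy is defined over *bounded* (replace-one) neighboring datasets.  The
feature-norm and label-range assumptions are load-bearing: every sensitivity
below is derived from ‖x‖₂ ≤ 1 plus the label bounds, and `preprocess`
enforces them by per-row scaling x → x/max(1, ‖x‖₂) and min–max mapping of
regression labels to [−1, 1].  Per-row scaling (rather than column scaling
fitted on train statistics) guarantees the bound for any input including
unseen test rows; the label map is fitted on the training split and applied
with clipping to the test split.  The exact normalization recipe is a free
choice — any map into the admissible region yields the same guarantee — and
per-row scaling is the one that needs no fitted state.

## Sensitivities and calibration

Per-order L2 sensitivities (replace-one):

* linear: Δ₀ = 1/N, Δ₁ = 4/N, Δ₂ = 1/N;
* logistic: Δ₀ = 0, Δ₁ = 1/N, Δ₂ = 1/(8N).

Δ₂ bounds the *spectral* norm of the rank-two difference
x_N x_Nᵀ − x'_N x'_Nᵀ; the test suite verifies both soundness (brute-force
maxima over random neighbors never exceed the bounds) and tightness
(explicit adversarial pairs achieve them to 1e−12).

Scheme-wide baselines: the classic functional mechanism uses the single L1
sensitivity Δ_fm = (2/N)(1+D)² (linear) or (1/N)(D²/4+3D) (logistic) with
Laplace(Δ_fm/ε) noise on every coefficient; the relaxed variant uses the L2
sensitivity Δ_rlx = (2/N)√(1+4D+D²) (linear) or (1/N)√(D²/16+D) (logistic)
with Gaussian noise.  The relaxed mechanism's published analysis invokes an
extended Gaussian mechanism whose exact constant is not reproduced here; the
standard calibration τ = (Δ/ε)√(2 ln(1.25/δ)) is used for both Gaussian
schemes, which if anything flatters the baseline.

The Gaussian calibration is stated for ε < 1; larger ε is accepted with a
warning.  The joint release of the three coefficient orders is calibrated
with each order at the full (ε, δ), matching the published algorithm; a
stricter reading would compose the three releases, which would scale all
τ_j by a common factor and change no qualitative comparison.

Budgets can be given as (ε, δ) or directly as the per-unit-sensitivity
noise multiplier σ = τ/Δ = √(2 ln(1.25/δ))/ε.  The experiment sweeps use σ
as the common x-axis so all mechanisms face noise proportional to their own
sensitivity at the same implied privacy level.

## Minimizing noisy quadratics: repair and stabilization

Additive noise can make M indefinite.  Symmetry is preserved by drawing the
matrix noise as an upper triangle (diagonal included, each entry drawn once)
mirrored below; positive semi-definiteness is restored by eigen-decomposing
and projecting negative eigenvalues to zero.  If *every* eigenvalue is
negative the projection returns the zero matrix, the result is flagged, and
minimization fails explicitly when the linear term is non-zero — this
degenerate case has no principled resolution and is surfaced, not papered
over.

Minimization is closed-form: w = −(2M)⁺α via the pseudoinverse, so
noiseless fits equal ordinary least squares exactly and no optimizer
nondeterminism enters the tests.

One further numerical step applies to the per-order Gaussian family
(`gaussian_fm_fit`, `cape_fm_fit`, `conventional_decentralized_fit`):
eigenvalues of the repaired M below the noise spectral edge 2·sd·√D (sd =
the per-entry noise level of M for that fit) are dropped before the solve,
keeping at least the top eigenvalue.  The rationale: eigenvalues of a
symmetric noise matrix concentrate within ±2·sd·√D, so curvature below that
edge is indistinguishable from noise, and the eigenvalue projection
necessarily strands some of it just above zero — inverting those
near-nulls amplifies both signal and noise without bound.  (At, e.g.,
N = 2000, D = 20, ε = 0.5 the Gram spectrum λ ≈ 1/D sits exactly at the
τ₂ edge and the unstabilized solve is dominated by these artifacts.)  The
truncation is deterministic post-processing of privatized quantities (no
privacy cost), and it vanishes identically at zero noise, so all exactness
contracts are preserved.  The `fm` and `rlx-fm` baselines are *not*
truncated: they are reproduced exactly as published (repair + pinv).  For
them the entire spectrum lies below their much larger noise edge, so the
same truncation would degenerate to a rank-one noise solve and erase the
distinction between the two baselines rather than stabilize them.

Package-wide tolerance conventions: exact-symmetry checks at 1e−12, PSD
assertions at −1e−10, oracle equivalences at 1e−10 (costs) and 1e−8
(minimizers).

## Noisy gradient descent

The iterative baseline perturbs per-iteration gradients of the *exact*
(unapproximated) cost: per-sample gradients clipped to L2 norm ≤ C
(default 1), averaged (replace-one sensitivity 2C/N), Gaussian noise of sd
(2C/N)·σ added per coordinate, fixed step (default 0.5), fixed iteration
count (default 100 in sweeps; 1000 in the privacy-loss headline).  These
constants are config-exposed; the underlying method is under-specified in
the literature it represents, and the defaults were chosen once as
conventional values.  The overall privacy loss is the RDP composition
evaluated at the optimal Rényi order, with δ_r set equal to δ.  Natural
logarithms are used throughout the accounting.

## CAPE: correlated noise for decentralized data

S sites hold equal disjoint shards (the symmetric setting; uneven N/S drops
the remainder rows).  Each site s perturbs its local coefficient arrays
with e_s + g_s, where the e_s are jointly generated, zero-sum across sites
(per-entry variance (1−1/S)τ_s²) and g_s is local (variance τ_s²/S).  Site
noise levels use the *local* sensitivities Δ_j(N_s).  Each individual
release then carries the full τ_s² a standalone release would need, while
the aggregator's average retains only the g-terms: variance τ_s²/S², equal
to the pooled-data calibration because Δ_j(N/S) = S·Δ_j(N) for these
1/N-type sensitivities.  The conventional baseline (each site adds full
independent noise) aggregates to τ_s²/S — worse by exactly a factor S,
which is the gain the accounting module reports.

The secure-aggregation protocol that lets sites compute Σê_s without
revealing individual draws is simulated functionally: the draws are
centered in the clear, with the contract that only the sum would leave the
sites in a deployment.  The privacy statements rest on the noise
statistics, which are identical; the cryptographic layer (secret sharing,
security parameter, threshold) is out of scope.  PSD repair happens once,
at the aggregator.

The colluding-adversary accounting (threshold S_C = ⌈S/3⌉−1) models the
privacy-loss variable of the colluders' view as N(μ_z, 2μ_z) and reports
the Gaussian tail bound δ = (2σ_z/(ε−μ_z))·φ((ε−μ_z)/σ_z).  The published
μ_z expression is typeset ambiguously in its source; the grouping adopted
here,

    μ_z = S³/(2 τ_s² N²) · [ (1+S)/(S−S_C) + 2/(S−S_C)
                             + 9(S−S_C)S_C² / (2S(1+S) − 3S_C²) ],

keeps every term positive for S_C ≤ S/3 (so μ_z > 0 always, as the theory
requires), and the tests of this quantity are deliberately property-based
(positivity, σ_z² = 2μ_z, δ strictly decreasing in ε) rather than
value-based.  δ is clamped to (0, 1) with a warning when ε ≤ μ_z.

## Synthetic data

The generators emulate the structure of preprocessed tabular study data:
features i.i.d. uniform on [−1, 1]^D, each row scaled onto the unit ball;
regression labels x ᵀw* + N(0, 0.05²) clipped to [−1, 1]; classification
labels Bernoulli(sigmoid(xᵀw*)).  The default true-weight norm is 3, chosen
so labels span most of [−1, 1] — mirroring what min–max scaling does to
real labels — and so the zero predictor is far from optimal; a much weaker
signal would make shrinkage-like behavior of heavily noised baselines look
spuriously competitive.

What the generator does *not* emulate: correlated or heavy-tailed features,
anisotropic Gram spectra, label imbalance, covariate shift between sites
(shards are random, hence exchangeable).  Passing tests therefore
demonstrate the mechanisms' noise calibration, aggregation identities and
relative ordering under controlled conditions, not performance on any
particular real dataset.  Notably, the isotropic Gram spectrum (all
eigenvalues ≈ 1/D) is the *hardest* case for the spectral-edge phenomenon
described above, so the stabilized solver is exercised in its least
favorable regime.

## Evaluation protocol

90:10 train/test splits; MSE (unclipped linear predictions) for regression,
accuracy for classification with the prediction 1{xᵀw ≥ 0} (the tie z = 0
rounds sigmoid(0) = 0.5 up to class 1).  Sweeps fix δ = 1e−5 and ε = 0.5
unless swept, average 10 runs by default, and derive every run's seed from
(seed_base, grid index, mechanism index, run index), so a re-run reproduces
the CSV byte-for-byte.  The trend tests draw a fresh dataset per seed, so
medians average over data geometry as well as mechanism noise; problem
sizes there (N = 2000, D = 20 linear / D = 13 logistic, 200 seeds; variance
audits at D = 3 with 10⁴ repetitions) were chosen as the smallest at which
the compared quantities separate cleanly from Monte-Carlo error.

## Known limitations

* The all-negative-eigenvalue case after noising is flagged, not solved.
* The relaxed mechanism's extended-Gaussian constant is approximated by the
  standard calibration (see above).
* The CAPE δ-accounting transcribes an ambiguously printed expression and
  should be treated as qualitative; its variance accounting (the part the
  fits rely on) is exact and verified by simulation.
* Logistic fits optimize the quadratic surrogate, not the exact likelihood.
* No regularized objectives, higher-order (J > 2) expansions, categorical
  encodings or missing-data handling.
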