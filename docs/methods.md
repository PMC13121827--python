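# Methods

## Model

For respondent *i* and one item, the measurement model is a GLM on the
linear predictor β₀ + β_θ θᵢ + β_η ηᵢ (+ Zᵢβ_z + θᵢZᵢβ_θz when group terms
are included), with identity link for continuous responses (residual
variance σ² profiled at its MLE RSS/N so that likelihood-ratio quantities
are internally consistent) and logit or probit links for binary responses.
θ̂ always enters as a fixed covariate: all fitting is conditional two-step
estimation, and uncertainty in θ̂ is not propagated. Binary-link fits use
Newton/Fisher scoring with step halving, stopping at score max-norm 1e-8
(cap 100 iterations); any coefficient exceeding 30 in magnitude during
fitting raises a separation error rather than diverging silently.

## The objective and its closed form

The surrogate weight vector w (unit norm, for identifiability) minimizes
Q(w) = 2(ℓ_full − ℓ_reduced), the likelihood-ratio statistic for the
grouping variable given (1, θ̂, η̂). The factor 2 puts Q on the χ² scale, so
detection and correction share units: after refitting with the surrogate,
the per-item group LRT *is* the achieved Q.

For the identity link, project Y, Z and the features onto the orthogonal
complement of span{1, θ̂} and orthonormalize the feature block by SVD
(components below 1e-10 of the leading singular value are dropped and
reported, never imputed). With a = F̃ᵀỸ, b = F̃ᵀZ̃, c = Z̃ᵀỸ,
Frisch–Waugh reduces Q(w) = 0 to the cross-moment equation
(wᵀa)(wᵀb) = c on the unit sphere. The bilinear form has range
[(aᵀb − ‖a‖‖b‖)/2, (aᵀb + ‖a‖‖b‖)/2], so an exact zero exists iff
|2c − aᵀb| ≤ ‖a‖‖b‖ (the solvability condition; its margin is reported).
Writing ψ for the angle of b relative to a and κ = (2c/‖a‖ − bᵀa/‖a‖)/‖b‖,
the two root directions in span{a, b} are φ = (ψ ∓ arccos κ)/2: the root
nearer a (η₁) aligns with the projection of Ỹ onto the feature span and is
returned by default; the root nearer b (η₂) aligns with the projection of
Z̃ and is available for diagnostics. Collinear a, b and zero-vector edge
cases are handled explicitly; when the condition fails, the solver falls
back to the numeric minimizer and flags the solution, since a best-effort
minimum is the useful contract. The root formulas are certified in the test
suite against an exhaustive 10⁶-point angle-grid search (K = 2) and a
dual-OLS oracle.

The returned surrogate values are the component of F·w orthogonal to
span{1, θ̂}. The surrogate is identified only up to components in that span
(the model's intercept and trait term absorb them, and Q is unchanged), and
orthogonality guarantees that adding the surrogate cannot alter the
fitted trait slope in the linear calibration — hence Fisher information of
θ can only increase there. Without this, a surrogate containing
trait-aligned content (inevitable when features nearly reproduce the
response) cannibalizes the trait coefficient at calibration.

## Numeric minimization

For nonlinear links the K-vector is optimized unconstrained with
normalization inside the objective (smooth, no manifold machinery), by
L-BFGS with analytic gradients from the envelope theorem: at the inner-fit
optimum, dℓ*/dη = β̂_η · score(linear predictor), so each gradient costs no
extra fits. Ten random unit-norm restarts plus a warm start from the linear
closed form on the same data; inner fits are warm-started across
iterations; a restart must improve the best objective by more than 1e-9 to
replace it, keeping ties on flat zero sets stable. Multiple grouping
variables minimize the sum of single-variable objectives; non-uniform DIF
passes [Z, θ̂∘Z]. The sign of w is fixed by corr(η̂, Ỹ) ≥ 0, consistent
with preferring η₁.

## Detection and scoring

Per-item DIF screening is the LRT with df = M (uniform) or 2M (non-uniform)
for M grouping variables, α = 0.05 per item by default (no multiplicity
adjustment, matching per-item reporting practice; Benjamini–Hochberg is
available). Items whose fits separate are reported untestable rather than
crashing. Initial trait estimates come from the anchor (assumed DIF-free)
items — one-factor ML factor scores for continuous responses; for binary
responses 2PL marginal ML via Bock–Aitkin EM (41 Gauss–Hermite nodes,
standard-normal prior, parameter-change tolerance 1e-4, cap 500 cycles)
followed by per-respondent MLE. When no anchor set is given, all items
serve as anchors. Trait estimates are standardized to mean 0, variance 1
each pass, sign fixed by non-negative correlation with the total score; the
per-respondent MLE is solved by damped Newton on [−6, 6] (standard-normal
latent scale; monotone likelihoods — all-correct/all-incorrect patterns —
return the bound). Calibrated scoring models never contain the grouping
variable. The iterative procedure (detect → solve → calibrate → re-score)
stops when successive trait vectors correlate ≥ 0.99 (Pearson), cap 10
iterations, returning the best iterate with a flag if it oscillates.

## Synthetic-data generator

Each replication: a focal fraction (default 0.5) of N respondents; θ normal
within group with means (0, −0.5) and unit variance; item intercepts
uniform on (−1, 1) and trait slopes on (0.8, 2.0); per item, K = 10
features drawn from a group-shifted multivariate normal and whitened so the
pooled sample covariance is exactly the identity; true nuisance trait
η\* = F·w\* with Exp(1) weights scaled to unit norm (so η\* has unit pooled
sample variance); responses generated from the GLM with the DIF effect
entering *only* through the nuisance slope β_η ~ U(0.5, 1.0) ("large", or
U(0.2, 0.4) "small") on the DIF items — the direct group coefficient is
zero, so DIF is purely distributional. The focal-group feature mean shift
is 0.75 on the first three coordinates, making the group separation on the
nuisance dimension about half a standard deviation — the same magnitude as
the trait separation — which yields clearly detectable but not degenerate
DIF at N = 2000. For the identity link the noise-free linear predictor
(noise variance 0.25) is appended as one extra feature column, emulating
process data's near-perfect response predictability without tying the
ground-truth nuisance trait to realized noise. Non-uniform DIF gives the
focal group a diagonal feature covariance with Exp(1) eigenvalues and adds
a θ×Z interaction coefficient on DIF items. Defaults: 20 items, 5 DIF
items, N = 2000, all constants exposed in `SimulationConfig`, fully
deterministic given the seed.

What the generator does *not* emulate: raw action sequences and their
feature extraction, missing responses, polytomous credit, nonlinear
feature–nuisance maps, and multi-form designs. Passing tests therefore show
the estimator recovers a *linear* nuisance structure under a correctly
specified link; they say nothing about feature-extraction quality on real
log files.

## Evaluation conventions

Five replication-level criteria: objective before (no-surrogate LRT) vs
after (achieved Q); nuisance-trait recovery; item-parameter MSE; Fisher
information of θ before/after (identity: β_θ²/σ²; binary links: the sample
mean of β_θ² w(p̂) — the mean, not the sum); and the between-group
sum-of-squares of scoring bias, n_R(b̄_R − b̄)² + n_F(b̄_F − b̄)² with
b = θ̂ − θ.

Three conventions deal with latent-scale indeterminacy. (1) Recovery is
the absolute correlation between the θ̂-residualized surrogate and the
θ̂-residualized truth: the surrogate is identified only up to sign and up to
span{1, θ̂}. (2) Item-parameter MSE applies metric linking first — the
estimated trait (and surrogate) relate to the generating latents by an
affine map estimated by OLS of truth on estimate, and fitted coefficients
are re-expressed on the generating metric before squaring errors; without
this, a location artifact of order 0.1 dominates the intercept MSE.
(3) For the scoring-bias comparison both arms' scores are affinely aligned
to the true trait's marginal mean and SD (group membership plays no role),
removing a shared calibration-scale group artifact that otherwise
randomizes the corrected-vs-uncorrected comparison; an estimate equal to
the truth still yields exactly zero. The bias comparison scores from the
DIF items only and runs at the 10-DIF-item setting, because a bounded MLE
from very few binary items parks a large fraction of respondents on ±6.

Sample-size comparisons are paired by subsampling: the small-N dataset is
the first-N-respondent view of the large-N replication, sharing item
parameters, weights and DIF effects, so paired differences isolate the
sample-size effect.

## Known limitations

Two-step conditional estimation leaves an MSE floor that does not shrink
with N: the anchor-based trait estimate carries fixed per-respondent error,
part of the group-shifted nuisance trait lies along θ̂ (and is excluded from
the orthogonalized surrogate), and that confounded slice loads on the trait
slope. At N = 2000 the floor is already comparable to the sampling
variance, so per-replication sample-size comparisons of parameter MSE are
noisy even though the expected MSE decreases. Bounded MLE scoring
saturates extreme response patterns at ±6, capping trait-recovery
correlations around 0.82 for 20 binary items (EAP would score higher but is
out of scope). DIF reduction is limited to the part mediated by the
features: the trait-measurement-error component of an item's group effect
is not feature-predictable and is minimized only in sample, not removed in
population. With K features and one grouping variable the in-sample
minimum of Q overstates the removal slightly (optimization over K
directions); the post-correction LRT is therefore conservative as a test.
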