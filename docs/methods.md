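# Methods

## Kernels

Gram matrices are computed with `sklearn.metrics.pairwise` primitives and
wrapped in a `GramMatrix` carrying sample ids, so train/test alignment is
checked rather than assumed. Square Grams are symmetrized exactly and
validated as PSD (smallest eigenvalue ≥ −1e−8 × largest); `validate_psd`
repairs borderline matrices by adding jitter·I, escalating by powers of
ten up to 1e−2, and logs every repair.

The radial kernel is exp(−σ‖x−y‖²/2). Some R kernel libraries omit the /2
(`rbfdot` uses exp(−σ‖x−y‖²)); a `kernlab_convention` flag on the spec
switches to that parameterization. Cosine normalization
K̃ᵢⱼ = Kᵢⱼ/√(KᵢᵢKⱼⱼ) is available for linear/polynomial kernels and off by
default.

Clinical kernels operate per feature and are averaged over the feature
subset, which keeps multi-feature nominal/ordinal Grams inside [0,1].
Ordinal inputs are integer level codes (a user-supplied level order can be
mapped with `encode_ordinal`); the range r defaults to the observed span.
A mixed stage+age clinical kernel is expressed as an equal-weight
`combine_grams` of the two single-feature kernels rather than a dedicated
operation.

## SVM core

`solve_svm_dual` delegates the box-constrained QP to libsvm
(scikit-learn `SVC`, precomputed kernel) and then reconstructs and
certifies the solution itself: dual coefficients from `dual_coef_`, the
dual objective Σα − ½αᵀ(yyᵀ∘K)α, and the bias averaged over unbounded
support vectors (midpoint of the KKT feasibility interval if every
support vector is at the box boundary). libsvm's epsilon bounds KKT
violation rather than objective gap, so the requested tolerance is passed
down divided by ten; the test suite checks the attained objective against
an independent SLSQP solve of the same dual to 1e−6 on random instances.
Class labels are encoded by sorted order (first class → −1) and the
mapping is stored on the model.

Cross-validation is stratified k-fold with a fixed seed; the full Gram per
kernel is computed once and sub-indexed per fold. The best (kernel, C)
cell is the highest mean accuracy with ties broken by grid order. The
default C grid is {0.01, 0.1, 1, 10, 100} — no principled wrapper-method
cost rule exists, which is exactly the gap the DAL cost mapping addresses.

## Wrapper MKL

Both wrapper solvers start from uniform weights η = (1/M, …, 1/M) and
treat J(η) = the optimal SVM dual value as the objective to minimize over
the simplex; by Danskin's theorem ∂J/∂ηₘ = −½αᵀ(yyᵀ∘Kₘ)α at the SVM
solution.

*SEMKL* applies the closed-form update ηₘ ← ‖fₘ‖/Σₖ‖fₖ‖ with
‖fₘ‖² = ηₘ²αᵀ(yyᵀ∘Kₘ)α, stopping at max|Δη| < 1e−4 or 100 iterations
(defaults sized so the benchmark runs in seconds; both configurable).
The multiplicative update reaches a zero weight only asymptotically, so
after the loop a guarded boundary polish tries exact zeros for weights
below 1e−2 and keeps them only when the objective does not get worse.
Weights below 1e−8 are zeroed and the vector renormalized.

*SimpleMKL* takes the reduced gradient with the largest-weight component
as pivot (ties → lowest index), clips descent components that would drive
a zero weight negative, and line-searches along the direction —
golden-section on [0, max feasible step] with Armijo backtracking as
fallback, each candidate step costing one SVM solve. It stops when the
relative duality gap (maxₘ Sₘ − ΣₘηₘSₘ)/2|J| falls below 0.01 or after 200
SVM solves (defaults; configurable). A stall in the line search
terminates with `converged=False` rather than looping.

Known limitation: with near-duplicate kernels the weight split is
unidentifiable and J(η) is nearly flat, where SEMKL's fixed-point
iteration converges very slowly; the duplicate-kernel tests therefore
assert prediction invariance, not the split.

## Sparse DAL solver

`dalmkl_fit` attacks min Σᵢℓ(yᵢ, Σₘ(Kₘaₘ)ᵢ + b) + CΣₘ‖aₘ‖_{Kₘ} with
‖a‖_K = √(aᵀKa), using augmented-Lagrangian (proximal-point) outer
iterations on the dual. The inner objective in the dual vector α is

    Σᵢ ℓ*(−αᵢ) + (1/2γ) Σₘ (‖aₘ + γα‖_{Kₘ} − γC)₊² + (1/2γ)(b + γΣᵢαᵢ)²,

minimized in t-space (tᵢ = yᵢαᵢ ∈ [0,1]) by a projected Newton method
with Bertsekas-style two-metric safeguards (an ε-band of binding
variables takes gradient steps) and Levenberg–Marquardt damping adapted
to line-search progress — the free-block Hessian can be near-singular
because the hinge conjugate is curvature-free and smooth kernels are
close to rank one. If the Newton iteration stalls, an L-BFGS-B pass over
the same objective is tried before the step is judged.

Loss conjugates: hinge ℓ*(−α) = −yα on the box yα ∈ [0,1]; logistic
ℓ*(−α) = t log t + (1−t)log(1−t), smooth on the open interval (t clamped
to [1e−10, 1−1e−10]). Because the hinge conjugate is polyhedral its inner
minimizer can be non-unique; a proximal term (1/2γ)‖t − t_prev‖² (the
standard proximal-method-of-multipliers regularization, vanishing as γ
grows) makes it unique and well-conditioned.

Outer updates soft-threshold each block, aₘ ← ST_{γC}(aₘ + γα) with
ST_c(q) = max(0, 1 − c/‖q‖_K)q, giving *bitwise-zero* inactive blocks,
and step the bias multiplier b ← b + γΣαᵢ. The proximity schedule starts
at γ=1 and multiplies by 4, capped at 1e6. Exact proximal steps cannot
increase the primal objective, so a primal increase is diagnostic of
inner-accuracy failure: the step is discarded and γ backed off (proximal
point still converges at fixed γ); the trace of accepted objectives is
therefore monotone by construction and the `converged` flag reports only
a met tolerance. The inner tolerance scales linearly with γ, matching how
the inner gradient scales.

Reported kernel weights are block norms ‖aₘ‖_{Kₘ} normalized to sum to 1,
for comparability with the wrapper methods. `estimate_wrapper_cost`
returns maxᵢ|αᵢ| of the DAL dual — the cost at which the wrapper box
constraint is tight at the DAL solution's largest dual coefficient. This
mapping is this package's convention; it is validated by cross-solver
prediction agreement (≥95% on easy problems), not by any closed-form
identity.

## Prioritization

Feature ranking uses Welch's t-test (unequal variances) or the
Mann–Whitney rank-sum test; constant features get p = 1 and a flag rather
than silent removal; ordering is ascending p with ties broken by feature
id. Kernel screening keeps a candidate only when its best cross-validated
accuracy is *strictly greater* than the no-information rate: accuracy
exactly equal to the NIR is the signature of a classifier collapsed onto
the majority class, the very case screening exists to remove. When no
candidate survives the pipeline halts explicitly.

Survival dichotomization excludes right-censored patients, enumerates
cutoffs at midpoints between consecutive distinct event times, requires
the survivor proportion in [0.4, 0.6], and picks the feasible cutoff
closest to 0.5 (ties → smaller cutoff). Infeasibility raises rather than
returning an out-of-band split. This procedure ignores the censoring
mechanism entirely — it is a pragmatic binarization, not a survival
model, and any downstream accuracy inherits that bias.

Everything here consumes training rows only; the workflow computes the
split first and passes train rows to ranking and screening, and a
regression test verifies that selecting on train+test rows changes the
selected set.

## Synthetic data

*Gaussian benchmark.* Group 1: 50 draws from N((5,5), I). Group 2: 50
draws with covariance [[1,−0.5],[−0.5,1]] and mean swept over
(−4,−4)…(4,4) in unit steps (9 configurations). Kernels: radial σ=2
(wiggly) and σ=0.04 (smooth). The most-overlapping printed configuration
still has group means 1.4 apart, so an optional tenth configuration puts
group 2 exactly on (5,5) — the genuinely "no information beyond
covariance shape" regime used for the near-chance check. Test sets are
independent draws of the same size; 30 replicates by default; the
replicate seed derives from (master seed, configuration index, replicate
index) and is recorded in the output. Wrapper methods run at C=1 and DAL
at C=0.05 in the sweep (neither cost is prescribed by the design; these
are the package defaults).

*Two-source omics generator.* Stage ~ uniform{1..4} and age ~ N(0,1)
drive a binary prognosis through a logistic link (coefficients 0.8 per
centred stage level and 0.8 per sd of age — a moderately informative
clinical picture, by itself worth ≈0.6–0.65 held-out accuracy at
n = 200). Ten of 300 expression features shift by 0.8 sd between outcome
groups — a strong but not overwhelming 10-gene signature, likewise worth
≈0.65 alone after top-20 selection. Survival times are log-normal
(medians 60 vs 20 months, log-sd 0.5) with independent uniform censoring
at rate 0.2. Because the two sources are conditionally independent given
the outcome, combining them should beat either alone — which is what the
integration test asserts, on means over 20 seeds.

*Noise-kernel problem.* Ten disjoint radial kernels over 5-feature
blocks, n = 60; the first two blocks carry a 2 sd class shift (a clear
positive control), the rest are pure noise. With the strongest
recommended penalty (C = 0.5) the block-norm optimum zeroes most noise
blocks exactly, which the sparsity test checks by majority over 20 seeds.
At weaker penalties more noise blocks are genuinely active at the optimum
(verified against a derivative-free solve of the same primal on small
instances), so sparsity counts are asserted as a monotone trend in C, not
as absolutes.

What these simulations do not emulate: real expression distributions
(heavy tails, correlation structure, batch effects), informative
censoring, or TCGA sample sizes. Passing them shows the solvers and the
workflow do what they claim under controlled conditions, not that any
particular clinical accuracy is attainable.

## Problem sizes and numerical choices

Simulation studies run at n = 100 training samples (benchmark), n = 200
(omics), n = 60 (sparsity), 20–30 replicates — sizes chosen so the full
study suite completes in minutes while keeping Monte-Carlo error well
inside the asserted margins. Solver tolerances used in near-exact
comparisons (oracle equivalence) are tightened from the fast defaults to
max_iter 2000 / tol 1e−7; degenerate inputs (single-class labels,
all-zero duals, misaligned ids, non-PSD Grams beyond repair) raise typed
errors rather than propagating NaNs. CSV artifacts are written with fixed
6-decimal weight formatting so identical runs are byte-identical.
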