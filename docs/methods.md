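# Methods

`pearlitr` estimates a sparse linear individualized treatment rule (ITR) from
observational data with many covariates and provides asymptotically valid
inference for its coefficients and its value. This note records the model, the
estimation and inference procedures as implemented, the numerical choices, and
the limits of what the package's simulations demonstrate.

## Model and estimand

Data are i.i.d. triples (X, A, Y) with covariates X ∈ R^p, binary treatment
A ∈ {−1, +1}, and outcome Y (larger is better). Under consistency, no
unmeasured confounding, and positivity, the value of a rule D: R^p → {−1, +1}
is V(D) = E[Y(D)], and the target is a linear rule D(x) = sgn(x'β) (with
sgn(0) = +1 throughout) maximizing V. Writing π(a;x) = P(A=a|X=x) and
Q(a;x) = E[Y|X=x, A=a], the doubly-robust per-observation weights are

    W_a = Y·1{A=a}/π̂(a;X) − [1{A=a} − π̂(a;X)]·Q̂(a;X)/π̂(a;X),

whose empirical average over rows assigned to arm a by D estimates V(D)
consistently when either the propensity or the outcome model is correct.
Splitting each weight into positive and negative parts gives nonnegative
per-row weights Ω₊ = (W₁)₊ + (W₋₁)₋ encouraging decision +1 and
Ω₋ = (W₁)₋ + (W₋₁)₊ encouraging −1; value maximization becomes weighted
binary classification, and replacing the 0–1 loss with the logistic surrogate
φ(t) = log(1+e^(−t)) yields the strictly convex penalized criterion

    β̂ = argmin_β  mean_i[ Ω₊ᵢ φ(xᵢ'β) + Ω₋ᵢ φ(−xᵢ'β) ] + λ‖β‖₁.

Strict convexity removes the need for a fixed-coefficient identifiability
constraint. The population minimizer β* of the unpenalized criterion is the
inferential target; under elliptically symmetric designs and mild conditions
on the contrast and main effect, sgn(x'β*) coincides with the optimal rule.

## Cross-fitting and pooling

Nuisances converge slowly when estimated flexibly, so the sample is split into
K folds (default K = 2). For fold k the propensity and per-arm outcome models
are fitted on the complement, the weights are formed on fold k's own rows with
the estimated propensity clamped into [0.1, 0.9], and β̂(k) solves the
penalized criterion on fold k alone with a cross-validated penalty λ_{n,k}.
The pooled estimate is the plain average β̂ = K⁻¹Σₖ β̂(k). Trimming applies
to *estimated* propensities only — never to simulated truths.

## De-correlated score inference

To test H₀: βⱼ* = 0 the score for coordinate j must be insulated from the
estimation error of the remaining p−1 coordinates. Per fold, a weighted lasso
projects Xⱼ on X₋ⱼ under the per-row curvature weights
h = Ω₊φ″(x'β̂(k)) + Ω₋φ″(−x'β̂(k)):

    ŵⱼ(k) = argmin_w mean[ h·(Xⱼ − X₋ⱼ'w)² ] + λ̃‖w‖₁,

and the fold score is the fold mean of ∇φ-factor times the projection
residual, evaluated at β̂(k) with coordinate j zeroed. Pooled across folds,
Sⱼ = K⁻¹Σₖ Sⱼ(k) is asymptotically N(0, σⱼ²/n) under the null even with
nonparametrically estimated nuisances. The variance is estimated by the pooled
empirical second moment of the per-row de-correlated score terms — the
standard plug-in for a score's asymptotic variance; the test statistic is
z = √n·Sⱼ/σ̂ⱼ with a two-sided normal p-value.

The one-step (debiased) coefficient applies a single Newton correction per
fold, β̃ⱼ(k) = β̂ⱼ(k) − Sⱼ(k)(β̂(k))/Îⱼ|₋ⱼ(k), with the partial information
Îⱼ|₋ⱼ(k) = mean[h·Xⱼ·(Xⱼ − X₋ⱼ'ŵⱼ(k))]; the score here is evaluated at
β̂(k), not at the null-modified coefficients. The pooled one-step estimate
and pooled information give the symmetric interval
β̃ⱼ ± z_{1−α/2}·σ̂ⱼ/(√n·Îⱼ|₋ⱼ). The same σ̂ⱼ serves the test and the
interval; for null coordinates the two candidate evaluation points coincide up
to the penalized estimate's own (typically zero) j-th coordinate. Multiplicity
over a coordinate set is handled by Benjamini–Hochberg q-values on request.
Degenerate inputs (all score terms zero, e.g. an identically zero outcome) are
flagged rather than producing spurious p-values, and folds with vanishing
partial information mark the coordinate's one-step interval unstable.

## Value inference

A single random half-split: the rule (with its own internal cross-fitting) and
the nuisances are fitted on the first half; the second half supplies
doubly-robust weights (nuisances refit on the full first half) and the
estimate V̂ = mean[W_{D̂(x)}] with plug-in variance σ̂_V² = mean[(W_{D̂} − V̂)²]
and normal interval V̂ ± z_{1−α/2}·σ̂_V/√n₂. One split only: repeated-split
aggregation would narrow the interval but is out of scope. Margin conditions
near the decision boundary (a vanishing treatment effect on a non-null region)
are assumed, not testable from data.

## Synthetic benchmark designs

Two generative designs with X ~ N(0, I_p), Y = A·Δ(X) + S(X) + ε, ε ~ N(0,1),
and fixed patterns β_opt = (1,1,−1,−1,0,…), β_S = (−1,−1,1,−1,0,…),
β_π = (1,−1,0,…):

* Scenario I (fully parametric): Δ = ξ·x'β_opt, S = 0.4·x'β_S,
  π(1;x) = expit(0.4·x'β_π);
* Scenario II (nonlinear effect and assignment): Δ = (Φ(ξ·x'β_opt) − ½)·
  (2(x₁+…+x₄)² + 2ξ), S = exp(0.4·x'β_S), π(1;x) = expit((x₁²+x₂²+x₁x₂)/4).

ξ ∈ [0.1, 1] scales the treatment effect; both scenarios share the linear
optimal boundary sgn(x'β_opt). The generator uses one root seed with
independent child streams for covariates, treatment, and noise, so datasets
are byte-reproducible. True values of rules are Monte-Carlo averages of the
noise-free conditional mean over fresh draws; for *linear* rules an
exact-in-distribution reduction draws only the four signal coordinates plus
the rule's orthogonal remainder, cutting cost by p/5 without changing the law.

What this generator does not emulate: correlated or heavy-tailed covariates,
discrete covariates, missing data, or exceptional laws with mass on the
decision boundary. Calibration results under these designs therefore certify
the procedure's internal correctness, not its behavior under real EHR-style
data.

## Numerical choices

* **Penalized surrogate solver** — FISTA with a spectral step (power-iteration
  bound on the curvature, φ″ ≤ ¼) and function-value adaptive restart;
  relative-objective tolerance 10⁻⁸, cap 10⁴ iterations; convergence is
  certified by the l1-subgradient KKT residual relative to the gradient scale,
  and failure is flagged, never silent. All-zero weights return the exact
  minimizer β = 0. Columns are standardized to unit scale inside the
  estimator (coefficients mapped back); no intercept in simulated designs.
* **De-correlation lasso** — cyclic coordinate descent on the weighted Gram
  matrix with an active-set strategy; same KKT certification.
* **Penalty selection** — K-fold CV (default 5-fold) over a log-spaced grid
  descending from the data-driven λ_max (the smallest penalty that zeroes the
  solution), default 50 points spanning two decades. λ_max adapts to the
  magnitude of the AIPW weights, which a fixed rate-anchored grid would not;
  the theoretical rate √(log p / n) fixes only the order, not the constant.
  Ties break to the smallest λ (less bias entering the one-step correction).
  For the de-correlation regression the two penalties share the same order,
  so the study harness searches one decade below λ̃_max with 8 points.
* **Nuisance estimators** — penalized parametric: l1-logistic
  (propensity) and per-arm l1-least-squares (outcome), penalties by internal
  CV on the training split only; nonparametric: distance-correlation
  sure-independence screening (budget ⌊n/log n⌋, capped at p) followed by
  Nadaraya–Watson smoothing with a product Gaussian kernel on standardized
  retained covariates, rule-of-thumb bandwidth 1.06·n^(−1/(4+d)). The
  screening statistic is the sample distance correlation (V-statistic,
  double-centered distance matrices), ties broken toward lower indices.
  User-supplied nuisance functions are accepted for oracle and
  misspecification studies.
* **Randomness** — every entry point takes one root seed; folds, CV splits,
  nuisance fits, and replications consume independent child streams.

## Study harness problem sizes

The Monte-Carlo studies use penalized-parametric nuisances with compact CV
grids (10 penalty points, 3 CV folds): calibration and null-CI coverage at
ξ=0.7, n=800, p=100, K=2 with 200 replications; value-interval coverage at
n=1600 (equal halves), p=100, 200 replications, per-replication truths from
10⁶-draw Monte-Carlo; double-robustness at n=4000, p=50, 20 replications per
nuisance setting; the null-law check at n=400, p=10 with oracle nuisances and
500 replications. These sizes were chosen to make a full study run cheap on a
single core while leaving every Monte-Carlo band at its nominal ±3 binomial
standard errors.

## Double robustness and its limits under isotropic designs

With one correct nuisance model the fitted direction aligns with β_opt
(cosine ≥ 0.85 in the studies, typically ≥ 0.99). A caution discovered while
designing the negative control: under the isotropic Gaussian design,
*direction* recovery is far more forgiving than double robustness — any
misspecification pair built from constant or index-form wrong models (zero
outcome model, constant or even sign-flipped propensities) still leaves the
population minimizer pointing along β_opt, because the design's elliptical
symmetry protects the direction and odd-moment symmetry annihilates
product-form distortions. A genuine failure needs wrong models whose errors
interact through a mean shift: the package's negative control pairs a
wrong-prevalence propensity (π̂ ≡ expit(1.5)) with a spurious main effect on a
null covariate (Q̂(±1;x) = 3x₅). Each is provably harmless alone — the
augmentation term is conditionally mean-zero under a correct propensity, and
the weight identity is exact under a correct outcome model — but together
they leak the spurious signal into the rule (population cosine drops to
≈ 0.77). Practitioners should not read directional robustness under
elliptical designs as evidence that both nuisance models are dispensable.

## Known limitations

* Logistic surrogate only; non-smooth surrogates (hinge, ramp) lack the
  Hessian the de-correlation step requires.
* Single-stage, binary treatment, linear rules; no dynamic regimes.
* No missing-data handling: ingestion rejects incomplete rows.
* The value interval can be conservative (single split uses only half the
  data for inference) and is not valid at exceptional laws.
* Global or multi-coordinate hypotheses are not implemented; per-coordinate
  tests with BH adjustment are the supported multiplicity control.
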