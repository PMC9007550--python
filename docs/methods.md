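# Methods

## The model

`relclogit` analyzes ranked responses from discrete choice experiments (DCEs)
with a **random effects latent class logit (RELCL)**: a latent class
conditional logit augmented with class-independent, factor-structured normal
random effects.

Each participant *i* completes *T* choice tasks; task *t* presents *M* = 3
unlabeled alternatives described by effects-coded attribute levels
**z**<sub>itm</sub>. Participants report a best and a second-best option.
Conditional on latent class *x* and individual random-effect scores
**F**<sub>i</sub>, the utility of alternative *m* is

    η_m | x, z_itm, F_i  =  Σ_p β_xp z_itmp  +  Σ_d Σ_p λ_dp F_id z_itmp

* **β<sub>xp</sub>** — class-specific part-worth utilities (one coefficient
  per attribute level, effects-coded so each attribute's expanded
  coefficients sum to zero; internally the model works with L−1 free
  contrasts per L-level attribute and expands deterministically, last level
  = −sum).
* **λ<sub>dp</sub>** — loadings tying attribute level *p* to random effect
  *d*. Each attribute belongs to exactly one *domain* and λ<sub>dp</sub> is
  fixed at zero when level *p*'s attribute is outside domain *d*. The
  loadings are class-independent: a single vector per domain.
* **F<sub>id</sub>** — i.i.d. standard-normal scores, independent across the
  D domains. Their scale is absorbed by λ, and (λ_d, F_d) → (−λ_d, −F_d) is
  unidentified; the canonical form fixes each domain's dominant expanded
  loading to be positive.
* Class membership follows a multinomial logit on participant covariates
  (cohort by default) with the last class as reference.
* No alternative-specific constants: the alternatives are unlabeled and
  presented in randomized order.

A ranking is scored as **sequential (exploded) logit** choices: softmax over
the 3 alternatives at the first choice times softmax over the 2 remaining at
the second, both at the same deterministic utilities. No Gumbel errors are
ever drawn explicitly — the two stages are fresh logit draws, which is the
data-generating process the exploded likelihood describes exactly.

The marginal likelihood of participant *i* mixes over classes and integrates
the random effects:

    L_i = Σ_x π_x(w_i; γ) ∫ Π_t P(first_it | x, F) P(second_it | x, F) dΦ_D(F)

All accumulation is in log space with log-sum-exp; an 8-class × 343-node
product underflows otherwise.

## Numerical integration

The normal integral uses tensor-product **Gauss–Hermite** quadrature
(probabilists' weight), default 7 nodes per dimension (343 nodes at D = 3).
A scrambled-Halton simulated-likelihood grid (default 200 draws) is available
as an alternative. Quadrature is deterministic, so refits reproduce
bit-identical results.

Gauss–Hermite error is not monotone in the node count — it oscillates between
consecutive rules while converging — and its accuracy degrades as the
per-participant random-effect posterior sharpens (long panels, large
loadings). At the package's default scale (12 tasks, loadings ≲ 1) the
7-node rule is adequate for estimation; oracle-equivalence checks against
Monte-Carlo integration use short panels where the 15-node rule is in its
high-accuracy regime.

The second-stage choice probability is computed by summing the remaining
alternatives' exponentials directly rather than subtracting the first
choice's term from the full-set sum; the subtraction loses all precision when
the first choice dominates.

## Estimation

Maximum likelihood via a hybrid schedule per random start:

1. **EM.** E-step: joint posteriors over (class × quadrature node) per
   participant. M-step: a weighted exploded-logit maximization for (β, λ)
   (L-BFGS-B on the expected complete-data log-likelihood with analytic
   gradients; a capped number of inner iterations gives a generalized EM
   step, which preserves monotonicity) and a weighted multinomial-logit
   maximization for γ. Runs until the log-likelihood gain falls below
   `tol` (default 1e-4) or `em_iterations` (default 250).
2. **Quasi-Newton refinement.** L-BFGS-B on the full marginal likelihood,
   default 50 iterations, using the exact score from Fisher's identity
   (the marginal score equals the posterior-weighted complete-data score).

Defaults mirror the published estimation protocol (250 EM + 50 NR iterations,
16 random starts; 150 starts to confirm a selected model). The test suite and
the acceptance script run a scaled schedule (8 EM iterations, inner M-step
cap 6, up to 200 quasi-Newton iterations, 3–4 starts): on the test-scale
problems this reaches the same optima as the full schedule at a fraction of
the cost, because the exact-gradient quasi-Newton phase does the heavy
lifting once EM has found the right basin.

Starting values: β ~ N(0, 0.5²) (dispersion wide enough to reach distinct
modes at test scale), small positive loadings on the domain mask, γ = 0.

**Canonical form.** Classes are relabeled by descending average membership
share (ties broken by the first β coefficient) and each domain's loading
vector is sign-flipped if its largest-magnitude expanded loading is negative.
Both operations leave the likelihood unchanged; canonicalization is
idempotent. For simulation studies, `align_parameters` instead matches an
estimate to a reference truth by minimum-cost class assignment plus per-domain
sign choice, resolving label switching before computing recovery error.

**Order constraint.** A two-level attribute flagged as ordered (testing
availability: weekdays-only vs every-day) carries an optional monotonicity
constraint — the expanded coefficient of the higher level is kept ≥ 0 via a
box bound on its free contrast in every class (default on). A class
indifferent to the attribute then shows a boundary estimate of 0.00.

**BIC.** BIC = −2·logL + k·ln(N) with N = number of participants by default
(the mixture-model convention for repeated measures); N = number of exploded
choices is selectable. The model-selection grid spans 1–10 classes × 0–3
random effects, flags the BIC minimum, and records per-cell failures without
aborting the grid.

**Standard errors** (optional) come from the numerically differentiated
observed information at the optimum, mapped to the expanded per-level scale
through the (linear) effects-coding expansion.

## Downstream analyses

* **Posterior summaries.** Class posteriors π_x(i)·∫exp(ℓ_i(x,F))dΦ
  normalized; modal class (ties to the lower index); empirical-Bayes factor
  scores as posterior means (and SDs) over the joint (class × node)
  posterior. The classification table's row *j* is the average posterior of
  each class among participants modally assigned to *j*.
* **Individual preference values** (density-plot export): expanded
  β of the modal class plus loading-weighted posterior factor scores. Values
  sum to zero within each attribute per participant; within-class spread per
  level grows with the magnitude of its expanded loading.
* **Bias-adjusted three-step analysis** (maximum-likelihood variant with
  modal assignment). Step 1 is the fitted model; step 2 assigns classes under
  the fitted measurement model with the class prior *marginalized over
  covariates* — classifying under a covariate-conditional prior makes the
  assignment error differential, which removes the attenuation the correction
  is designed for and causes over-correction (observed in calibration). Step
  3 maximizes Σ_i log Σ_k π_k(w_i) D[k, m_i] where D[k, j] = P(assigned j |
  true k) is estimated from the posteriors; the naive regression (D = I) is
  reported alongside for comparison. A singular D triggers a warning and the
  naive fallback. Reported with class 1 (the largest) as reference.
* **Factor-score regressions.** OLS of each posterior factor score on the
  covariates; collinear covariates are dropped with a warning. Because
  empirical-Bayes scores are shrunken toward zero, their regression slopes
  are conservative relative to the latent scores.
* **Concordance.** Modal assignments from two fits are cross-tabulated and
  classes matched by a Hungarian assignment maximizing the diagonal; the
  agreement proportion is reported after matching (chance level ≈ 1/X).

## The synthetic-data generator

There are no public data for the motivating study, so the generator is a
first-class module that emulates its conditions: 740 participants (300 female
barworkers, 440 male Kilimanjaro mountain porters), a 120-task / 10-block /
3-alternative design with per-participant task- and alternative-order
randomization, 12 ranking tasks each, 8 preference classes, and 3 domain
random effects (privacy & confidentiality; invasiveness & perceived accuracy;
accessibility & value). The default generating parameters are the published
8-class coefficient profile with its loadings, and a membership logit
reproducing the published class shares by cohort. Covariates (age, education,
marital status, HIV-testing history) are drawn independently from the
study-sample marginals — the joint covariate distribution is not published,
so only the marginals are emulated.

What the generator does *not* emulate: attribute-ranking warm-up and
dominance (comprehension) tasks, item nonresponse, joint covariate
dependence, any deviation from the exploded-logit response process (e.g.
inattention, fatigue over tasks), and D-efficient design optimization — the
design generator uses balanced random construction (each attribute's levels
cycled and shuffled, duplicate alternatives repaired, level frequencies
screened to within 20% of uniform). Estimation correctness does not depend on
D-efficiency; only the precision of a given sample size does. Passing tests
therefore demonstrate statistical correctness of the machinery under the
model's own assumptions, not robustness to the response-behaviour
misspecifications real survey data may carry.

## Test and validation scales

Fitting the full published scale (8 classes × 3 effects × 740 participants,
40-cell BIC grid, 16 starts) is a cluster-scale computation; the package's
validation uses scaled scenarios chosen to keep every property identifiable:

* default test scenario: 3 classes, 2 effects, n = 1000, class separation
  ≥ 1.0;
* parameter recovery: 2 classes, 1 effect, n = 1000, 10 seeded replicates
  (max |error| ≤ 0.15 on expanded β, ≤ 0.2 on loadings);
* model selection: grid over {1,2,3} classes × {0,1} effects at n = 400,
  10 replicates;
* three-step: 2 classes, 6-task panel (so classification error is
  non-trivial), n = 2000, membership slope 1.0;
* quadrature oracle: 20 participants × 6 tasks, D = 1, 15 nodes vs 200,000
  Monte-Carlo draws.

## Degenerate inputs and edge cases

* D = 0 collapses the quadrature grid to a single empty node: the same code
  path yields the plain latent class logit; X = 1 additionally drops the
  membership block, giving a plain exploded conditional logit.
* A start whose posterior underflows (non-finite likelihood) is abandoned
  and recorded; `fit` raises only if every start degenerates.
* A single-participant dataset converges (boundary estimates tolerated).
* Posterior ties in modal assignment resolve to the lower class index.
* Imported CSVs are validated strictly (duplicate rows, missing columns,
  alternative counts, exactly one first and one distinct second choice per
  task) with offending rows named in the error.

## Known limitations

* Loadings are class-independent and random effects are mutually independent
  standard normals; correlated or non-normal heterogeneity and scale
  heterogeneity are out of scope.
* M = 3 alternatives with a depth-2 ranking is assumed throughout the
  likelihood (the study design); deeper rankings would need an extended
  exploded likelihood.
* The three-step SEs do not propagate step-1 sampling error (standard for
  the ML variant).
* BIC sample-size convention is exposed but not auto-selected; participants
  is the default.
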