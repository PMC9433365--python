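# Methods

## Model

The observed outcome of one sequential-risk-task trial is a pair (y, c):
the number of cards at which the round ended and a flag for whether a loss
card ended it. The modeled quantity is the latent intention Z — the count
the participant would have reached voluntarily. The joint probability of an
observation factors into a parameter-free mechanics kernel Ω and a
parameter-dependent factor Θ:

* **Mechanics (Ω).** With `n_loss` loss cards placed uniformly among
  `n_cards` positions, the hazard of the k-th card being a loss card given
  k−1 survivals is the hypergeometric first-loss hazard
  p_k = n_loss / (n_cards − k + 1), and survival through k cards is
  S(k) = C(n_cards−k, n_loss) / C(n_cards, n_loss). An uncensored outcome
  (y, c=0) has probability S(y) and requires Z = y; a censored outcome
  (y, c=1) has probability S(y−1)·p_y for every Z ≥ y. Because Ω does not
  involve model parameters, censoring is exogenous: the mechanics factor is
  an additive constant in the log likelihood and is excluded from
  optimization (an `include_omega` switch exists, and a test verifies the
  estimates are identical either way).

* **Intention distribution (Θ).** A negative binomial with mean μ and
  dispersion δ (variance μ + μ²/δ), inflated at attractive outcomes: extra
  mass φ₁ at 0, φ₂ spread evenly over A = {4, 8, 10, 12, 16, 20, 24} (the
  geometric-pattern counts of the 8×4 card layout, with 10 included as an
  attractive round number), φ₃ at 31, with φ₄ scaling the smooth base
  distribution (Σφ_m = 1). The base distribution's mass beyond the deck is
  folded onto the top of the support: Pr(Z = 32) = φ₄·(1 − Σ_{j≤31} f(j)).
  This is the only treatment of the top cell under which the pmf sums to
  one exactly; it is asserted to 1e−10 for a thousand random parameter
  draws. Uncensored trials contribute the pmf at y; censored trials the
  survival P(Z ≥ y).

* **Link.** μ = softplus(η) = log(exp(η) + 1), computed via `logaddexp`.
  The link is positive everywhere and within 0.007 of the identity for
  η ≥ 5, so regression coefficients are read on the cards scale.

* **Heterogeneity.** Persons belong to latent segment s ∈ {1..S} with
  probability π_s; the linear predictor is η_its = α_s + x̃′β̃_s + x*′β*,
  where the segment-specific block x̃ is optional. The person-level
  likelihood mixes over segments before multiplying over persons.

## Covariate encoding

Categorical variables keep one reported coefficient per level under a
sum-to-zero constraint per variable (and per interaction family), so the
intercept is the expected intention of a person neutral on every predictor.
Internally each family is mapped onto an orthonormal sum-to-zero basis
(Helmert contrasts); optimization is unconstrained and per-level
coefficients with delta-method standard errors are recovered afterwards.
Interactions use the Kronecker product of the family bases, which doubly
centers the interaction coefficients (every slice sums to zero, matching
the ± symmetric patterns such encodings produce). Numeric covariates are
z-scored with the estimation sample's mean and standard deviation
(ddof = 1); the scalers are stored in the fit result and re-applied —
never re-estimated — when encoding new data.

Loss-experience lag variables (`loss_lag{j}` = yes/no depending on whether
trial t − j ended censored) are two-level categoricals; the first j trials
of a person have no defined lag and receive the neutral all-zero dummy row,
i.e. they sit at the categorical mean. This first-trial convention is a
package choice; nothing in the data pins it down, and with T ≥ 8 trials per
person it affects at most a couple of rows per person.

## Estimation

All parameters are transformed to an unconstrained space:

| natural | transformed | notes |
| --- | --- | --- |
| α₁ ≤ … ≤ α_S | α_s = Σ_{r≤s} α̃_r² | orders segments, removes label switching |
| φ (4 weights) | τ₁..τ₃ | multinomial logit, last category reference |
| π (S weights) | σ₁..σ_{S−1} | multinomial logit, last category reference |
| δ > 0 | log δ | |
| β | unconstrained basis coefficients | see encoding above |

The transform is a bijection on the interior (round-trip tested to 1e−10);
boundary weights (exact 0/1) raise an error. The cumulative-squares device
forces α_s ≥ 0 — a harmless restriction on the cards scale of this task,
though it could not represent a negative intercept.

The likelihood is maximized with a quasi-Newton search (L-BFGS-B) under a
strict relative stopping rule: iteration ends when the log-likelihood gain
falls below 1e−10·(|log L| + 1e−10). One Newton-Raphson step on a
central-difference Hessian (step 1e−4·(1 + |x|)) then pushes the gradient
toward zero; the step is kept only if it does not lower the log likelihood
by more than 1e−6, and the final gradient norm is recorded in the fit
result. The same observed-information Hessian provides standard errors,
mapped to the reported scale (α_s, π_s, φ_m, δ, per-level β) by the delta
method with a numerical Jacobian. A singular Hessian yields missing SEs
with a warning rather than a failure, and a segment share pinned below
1e−4 triggers a boundary warning rather than removal.

Start values are educated guesses: intercepts equally spaced over the
interior of the support (s·32/(S+1) for s = 1..S — one reading of "spread
uniformly over the possible outcomes"); inflation weights from the observed
excess mass at each inflated outcome over the linear interpolation of its
flanking non-inflated neighbours, floored at 1e−3; everything else neutral.
An optional warm start first fits a random subsample of 100 persons.
Every stochastic routine takes an explicit seed; fits are deterministic
given data and options.

Model evaluations deduplicate design rows, so a balanced design with eight
game settings costs eight (× S) distribution evaluations per objective
call regardless of the number of trials.

**BIC** is −2 log L + k·log(N) with N the number of *persons* — the
independent units of the likelihood. Segment selection walks S upward and
accepts a model while its BIC improves, every π_s ≥ 5%, and adjacent
intercepts differ by at least a threshold (default 1.0 card); the last
accepted S is returned with per-model diagnostics.

## Synthetic-data generator

`simulate` emulates the CCT study design: each person draws a segment from
π; trials come in balanced blocks of the eight canonical game settings
(gain ∈ {10, 30} × loss ∈ {250, 750} × loss cards ∈ {1, 3}) with the order
re-randomized per block; Z is drawn from the inflated distribution at
η_its; the loss cards are placed uniformly, and the trial is censored at
the first loss position L whenever L ≤ Z (y = L), else uncensored with
y = Z.

The built-in recovery parameter sets use N = 500 persons, T = 8 trials
(exactly one block), two segments, and true values
β = (2, −3, −6) or (6, −4, −7.5), α̃ = (3.39, 2.92) or (3.87, 2.83),
δ = 3, τ = (−3.5, −1.9, −2.1), σ = −0.4 — i.e. α = (11.49, 20.02),
φ ≈ (0.023, 0.115, 0.094, 0.768), π ≈ (0.40, 0.60).

**Game-setting coding.** The three game-setting coefficients apply to 0/1
indicators of the riskier level (gain 30, loss 750, three loss cards), so
the intercepts are the mean intentions in the benign baseline setting and
each β is the cards-scale shift of switching one factor. This coding was
identified empirically: pilot replications under ±1 contrast coding produce
gain- and loss-amount standard errors roughly half the reference values the
recovery study is checked against, while the 0/1 indicator coding
reproduces the full SD/SE profile of all ten parameters. Simulator and
fitter share the coding, so recovery metrics compare like with like.

The generator reproduces the mechanics and the model's own stochastic
structure; it does **not** emulate features of real cohort data such as
covariate-driven heterogeneity beyond the game settings, learning or
fatigue across trials, carry-over effects (unless built into η via lag
covariates), or missing data. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the model, not robustness to
misspecification.

The recovery study replicates simulate → fit (true values as start values,
for speed), excludes and counts non-convergent fits rather than retrying,
and reports per-parameter mean, median, SD, mean estimated SE, RMSE, MAD,
and 95%-CI coverage, plus the fraction of replications in which the
two-segment BIC beats the one-segment BIC. The test suite runs it at the
full design size (N = 500, T = 8) with 200 replications, which keeps the
whole suite within a few minutes on one CPU.

## Diagnostics

* **Point predictions**: the mixture expectation of Z, with prior weights π
  for unseen persons and posterior weights in-sample. RMSE and MAD are
  computed over uncensored trials only.
* **Predicted joint distributions**: P(Y=k, C=c) = Σ_ℓ Ω_{kℓ,c} Pr(Z=ℓ),
  the censoring-corrected distribution comparable to observed histograms;
  verified against exhaustive enumeration over intentions and loss-card
  placements.
* **Goodness of fit**: a chi-square statistic with adjacent cells pooled
  when the expected count falls below 5 (df = cells − 1, hence 31 on the
  full uncensored support), the Pearson correlation of the observed and
  predicted probability vectors over {0..31}, and the Hellinger distance
  (1/√2)·‖√obs − √pred‖₂.
* **Segment profiles**: posterior-weighted means of z-scored external
  scores per segment. Differences are tested with a Wald chi-square
  (df = S − 1) built from each weighted mean's variance via its effective
  sample size (Σw)²/Σw²; segments with effective size below 2 are excluded
  with a warning. This construction is a package choice; a simulation
  calibration (size ≈ nominal under the null, power > 0.9 under a strong
  signal) is its acceptance surface.
* **Category profiles**: per-person proportions over the four outcome
  categories (zero / attractive set / 31 / all), with outcomes in a special
  category splitting their weight equally between it and the catch-all.

## Numerical choices and edge cases

* All pmf work is done from `scipy.stats.nbinom` log probabilities;
  survival functions are reverse cumulative sums of the pmf, so they are
  nonnegative and monotone by construction.
* Zero-probability observations contribute −∞ to a segment's log
  likelihood (logged at debug level) rather than raising; a person is only
  problematic if all segments are impossible.
* Expected-value ties in the optimal-strategy calculator are real (the
  marginal expected value of one more card can be exactly zero); the full
  argmax set is returned and the smallest maximizer is the scalar summary.
* Hazards are clipped to [0, 1]; positions where survival is already zero
  make the clip unobservable.
* The deck size is a property of the game configuration (32 for the CCT),
  so other sequential tasks are representable by changing `cap` and the
  inflation sets.

## Known limitations

* The base negative binomial is defined on all nonnegative integers; the
  tail fold places its beyond-deck mass on the top cell rather than
  truncating and renormalizing. A truncated variant would change δ's
  interpretation slightly.
* α_s ≥ 0 by construction of the identifiability transform.
* Standard errors rest on the observed information; no bootstrap is
  provided.
* Segment selection thresholds (5% share, 1.0-card intercept gap) are
  conventions, not estimates; different thresholds can select different S.
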