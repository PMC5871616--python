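# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limits of `caretactics`.

## Study system and observation model

The unit of observation is the *bear-year*: one marked female in one
hunting-season year (the season anchors the annual census; survival spans
year *t* to *t*+1). Females provide maternal care for 1.5 or 2.5 years.
During the hunting season, members of family groups — a mother with
dependent cubs or yearlings, and yearlings still accompanying a 2.5-tactic
mother — are legally protected; everyone else is available for hunting. A
1.5-tactic female therefore cycles protected/available every other year
(interbirth interval 2), a 2.5-tactic female is available roughly 1 year in
3 (interbirth interval 3). Age classes: yearling, 2, 3, 4–8 (prime age),
9+.

## Mixed models

All binary analyses are Bernoulli-logit GLMMs with a single random
intercept, fit by marginal maximum likelihood with 25-node Gauss–Hermite
quadrature (`caretactics._glmm`); recruitment uses an NB2 (mean/dispersion)
log-link GLMM. Standard errors come from the inverse finite-difference
Hessian; CIs are Wald on the link scale, exponentiated for odds ratios.
The estimator is cross-checked in the test suite against `lme4::glmer` at
matched quadrature order (agreement to ~1e-3 on coefficients, variance and
log-likelihood) and against plain GLM fits in the zero-variance limit.
Variance components landing on the boundary are reported as 0 with a
`boundary` flag; quasi-complete separation is flagged, never fatal.

* **Weaning trend** — litter outcome (1 = 2.5 years of care) on centered
  weaning year, female random intercept; the exponentiated year
  coefficient is the annual odds ratio of long care.
* **Survival** — `survived ~ tactic + age_class + (1 | year)`, reference
  level yearling × 1.5-tactic; the tactic × age-class interaction enters
  only if a likelihood-ratio test has p < 0.05.
* **Recruitment** — `recruits ~ tactic + (1 | female)` on age ≥ 5
  female-years of tactic-classified females. A year intercept would be a
  natural second random term; the single-random-intercept estimator keeps
  the female term (the repeated-measures grouping) and omits year, which
  in the generator only perturbs survival.
* **Protection** — `survived ~ solitary + age + (1 | year)` on adult
  records, with age entering linearly (the exact age coding behind
  "controlling for female age" is unspecified; linear is the simplest
  choice and is documented here).

### Repeatability

For females with ≥ 2 weaned litters, an intercept-only logistic GLMM gives
the between-female variance σ². Latent-scale repeatability uses the
logit-link residual π²/3:

    r_latent = σ² / (σ² + σ²_resid + π²/3),

with the multiplicative-overdispersion residual σ²_resid fixed at 0 for
strictly binary data. The original-scale value back-transforms through the
link slope at the intercept (p = invlogit(β₀), m = p(1−p)):

    r_original = σ² m² / (σ² m² + p(1−p)),

i.e. the first-order (delta-method) mapping of the latent variance against
the Bernoulli residual variance. CIs are percentile bootstrap over females
(resampling females keeps litters nested), seeded; percentile rather than
basic intervals because the sampling distribution of r is bounded and
skewed.

### Rate table and bootstrap

Tactic × age-class rates are model predictions: survival cells are
inverse-logits of the linear predictor (random effects at zero — the
generator applies its year effect on the logit scale, so this conditional
prediction targets the configured rate); recruitment cells are marginal
means exp(γ + σ²_female/2), since a log-normal random intercept shifts the
population mean rate upward. Uncertainty is parametric: coefficient
vectors drawn from the asymptotic normal distribution of the fixed
effects, back-transformed per draw to the 14 cells, summarized by draw
means and 2.5/97.5 percentiles. Bootstrap means sit slightly off the
plug-in point estimates (Jensen averaging through the nonlinear links);
both are reported (`RateTable.point`), and the same applies one level up:
bootstrap-mean λ, R₀ and T differ by a few percent from the point-estimate
computation, R₀ most visibly.

Raw mortality rates (deaths/exposure by status and cause) carry
normal-approximation 95% CIs as the primary interval — the form that
matches the published presentation — with Wilson intervals reported
alongside (better behaved at small counts; the two agree to well within
rounding except at the smallest counts).

## Leslie matrices and summaries

Each tactic's life cycle is a 9×9 matrix: row 1 = (0, 0, 0, F₄₋₈ ×5, F₉₊)
with F = S·R (survive the year, recruit a yearling daughter next spring);
subdiagonal = (S₁, S₂, S₃, S₄₋₈ ×5); S₉₊ in the (9,9) corner. The 4–8
block is expanded into five explicit classes sharing one S and one F,
avoiding an arbitrary stay/advance split. R₅₋₉ = R₁₀₊ by default (age
class does not affect recruitment) but the API accepts distinct values.

λ is the Perron root: LAPACK eigenvalue refined by a bracketed root-find
on the renewal (Euler–Lotka) equation, which is strictly decreasing in λ
above the S₉₊ pole — this pins λ to machine precision, and the renewal
residual at the returned root stays below 1e-10 across plausible life
histories (property-tested). The identity degrades only in the
near-reducible corner (negligible fertility, λ → S₉₊), where float64
cancellation dominates; such matrices are outside the tested domain. R₀ is
computed two ways — dominant eigenvalue of F(I−U)⁻¹ and the closed-form
lifetime sum F₄₋₈(l₄+…+l₈) + F₉₊ l₉/(1−S₉₊) — which must agree to 1e-10.
T = ln R₀ / ln λ (λ = 1 raises an explicit error; the cohort generation
time is out of scope). The stable age vector is the normalized dominant
right eigenvector; the adult fraction sums classes age ≥ 4. Elasticities
(a_ij v_i w_j / (λ ⟨v,w⟩)) are provided as a utility; in this life cycle
the survival entries carry more elasticity mass than the fertilities,
which is why a survival subsidy can offset a large recruitment deficit.

## Hunting response

The pressure index h(year) = shot / available among marked bears; years
with no available bears give a missing (not zero) index. Survival is
regressed on h per tactic × age class by plain logistic regression (h is a
year-level covariate shared by all individuals in a year), and estimation
uncertainty is carried as 1000 draws from the asymptotic normal
distribution of (intercept, slope) — a parametric bootstrap standing in
for the posterior sampling used originally; both satisfy the same
prediction contract. For each draw and each of 12 grid pressures
(default: evenly spaced over the observed range), the five predicted
survivals enter the tactic's matrix with recruitment held fixed (only
survival responds to hunting), giving a λ distribution per pressure.
Cells with constant pressure or separation are flagged and the tactic
skipped with a note. The API accepts any year-level covariate, so a
population-density index can be substituted for h; no spatial density
estimation is included.

## Synthetic population generator

The generator is an individual-based annual cycle: January births →
spring weaning/family breakup and recruitment of yearling daughters →
hunting season → other-cause mortality → age increment. One seeded
generator drives every draw; females are processed in id order, so output
is bit-reproducible given the seed.

**Tactic process.** Each female carries a latent effect
u ~ N(0, `tactic_sigma`²) on the log-odds of 2.5-year care; each litter's
tactic is a fresh draw from invlogit(`p25_intercept` + `p25_trend`·(year −
start) + u), optionally overridden (probability `tactic_consistency`) by
repeating her first-litter tactic verbatim. Defaults: trend log(1.17) per
year (the published annual odds ratio); intercept −3.1, placing long care
at a few percent of litters at the study start and ~25% overall by the
study's end; `tactic_sigma` = 1.2733, chosen so the latent-scale
repeatability σ²/(σ²+π²/3) is 0.33, the published estimate;
`tactic_consistency` = 0 (pure latent process). Subadults are labeled by
the care they received; adults by their own tactic from first reproduction
onward — adult bear-years before first reproduction are labeled `unknown`,
as a field study cannot classify them, and are excluded from tactic-keyed
fits.

**Demographic rates.** `survival_by` (defaults: the published tactic ×
age-class means) is the *total* annual survival each class realizes at a
scalar calibration pressure (default: the mean of the pressure series).
Hunting acts first (probability h for available females,
`accidental_kill_prob` = 0.002 for protected ones); other-cause survival
is the residual hazard, computed by a deterministic cohort projection of
the protection-state cycle: for each first-birth age (4/5/6 with
probabilities 0.5/0.35/0.15), the availability path is walked with
survivorship weights discounted by the configured growth rate (young
adults are overrepresented in a growing observed population), yielding
per-class availability fractions and hence the residual survival, as a
fixed point. A class whose configured survival cannot be reached at the
calibration pressure raises a configuration error naming the class — with
the published defaults the binding class is the fully-exposed 2.5-tactic
3-year-olds (limit ≈ 4% pressure), which is why the default scenario is
lightly hunted (constant 0.025); the hunting-response analyses pass higher
pressure series explicitly and *intend* survival to fall below the
configured values away from the calibration point.

**Recruitment.** Litter size is drawn from {1:0.12, 2:0.42, 3:0.40,
4:0.06} (mean 2.4 cubs), sexes 1:1; only female yearlings enter the
recorded population (the first age class is yearling precisely to avoid
cub sex assignment). Cub-to-yearling survival per tactic is back-solved so
the mean recruits per age ≥ 5 tactic-classified female-year equals
`recruitment_by` (defaults 0.384/0.251): the cohort projection supplies
the event-year fraction, which sits near 1/interbirth-interval but carries
edge effects from first-birth phasing, survivorship and growth weighting
that a naive 1/cycle calibration would miss. Recruits are clamped at 3
(the observed range; the clamp binds with probability < 1e-3). A mother's
death takes her dependent cubs with her; care truncated by maternal death
before the scheduled weaning is recorded as lost-before-weaning, so
observed care durations never mix mortality into tactic consistency.
Pre-weaning litter loss is available (`litter_loss_prob`) but defaults to
0, matching the analysis assumption of no pre-weaning losses; nonzero loss
makes the recruitment calibration approximate.

**Year effects.** A shared annual N(0, `year_effect_sd`²) perturbation
(default 0.1) on the other-cause survival log-odds motivates the year
random intercepts in the fitted models.

**What the generator does not emulate:** spatial structure and density
dependence, male bears and infanticide as an explicit mechanism (it is
part of residual mortality), observation error (recapture of marked
females is treated as certain), and between-female heterogeneity in
recruitment beyond the reproductive cycle itself. Passing tests therefore
show that the estimators recover the generating process under the stated
structure, not that the field data meet it.

## Numerical and design choices

* Eigen tolerance: renewal-equation refinement to brentq xtol 1e-15;
  dominant root asserted real (imaginary part < 1e-9 relative).
* GLMM: 25 GH nodes; L-BFGS-B; σ bounded in [0, 50]; boundary flag below
  1e-3; separation flag at |β| > 15.
* Parametric draws use an eigendecomposition square root of the
  covariance (robust to near-singular Hessians); non-finite draws are
  rejected, > 1% rejections is an error, as is > 1% invalid matrices in
  demographic propagation.
* Exceedance probabilities over paired bootstrap draws count ties as 1/2.
* The consistent-vs-flexible age comparison is a pooled-variance Student's
  t-test on each female's mean observed age.
* The share of consistent females is reported both among multi-litter
  females and among all assigned females (the natural denominator is
  ambiguous; both are given).
* Mean care duration exactly 2.0 classifies as the 2.5-year tactic (the
  ≥ 2 rule).
* Problem sizes in the test suite (e.g. 200-replicate recovery and
  coverage runs at ~2000–5000 bear-years, 1000 random matrices) were
  chosen to give stable Monte Carlo checks at interactive runtimes.

## Known limitations

* One random intercept per model; crossed female × year effects are not
  fit.
* Wald/percentile intervals throughout; no profile likelihood.
* The λ(h) propagation treats the per-cell pressure slopes as
  independent across classes (they are fit independently, as in the
  original analysis); correlated year effects across classes are not
  carried into the prediction.
* The simulator's protection-state cycle is deterministic given the
  tactic sequence; skipped breeding years beyond litter loss are not
  modeled, so interbirth intervals are exactly 2 or 3 years.
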