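# Methods

## Data-generating model

Each replicate dataset holds k₁ randomised and k₂ non-randomised two-arm
studies. Per study: one arm size n (shared by both arms) drawn uniformly on
the scenario's integer range; a control-arm event probability
p_C ~ Beta(a, b) with (a, b) moment-matched to mean 0.04 and variance 0.001
(perioperative-mortality scale); arm mean ages x_T ~ U(75, 90) and
x_C ~ U(70, 85) for non-randomised studies, while a randomised study draws a
single age from U(70, 85) shared by both arms (randomisation balances the
covariate; the shared value only matters to the aggregate meta-regression,
and which range it comes from is configurable). The study log odds ratio is

    psi = theta + alpha_age * (x_T - x_C),

treatment risk p_T = expit(logit(p_C) + psi), and event counts are binomial.
Thus imbalance in age is the *only* bias channel: with alpha_age = 0, or
with identical age ranges in both arms, every study is centred on theta
(property-tested). Non-randomised age differences average +5 years, so the
mean non-randomised psi is theta + 5·alpha_age (+0.30 at alpha = 0.10,
+2.30 at alpha = 0.50, against theta = −0.20).

Six built-in scenarios cross alpha_age ∈ {0.10, 0.50} with three study
portfolios: 4+4 studies with all arms 100–500; 4 RCTs + 40 NRS; and 4+4
with NRS arms 500–1000.

Seeding: a dataset is a pure function of (scenario, seed). The master
`SeedSequence` spawns one child stream per study type, and all study-level
draws come from that type's stream in a fixed order, so datasets are
bit-reproducible and the randomised studies' draws do not shift when the
non-randomised count changes.

Arm sizes are re-drawn for every replicate dataset (they are part of the
sampling variability being studied), and are integers because the binomial
needs counts.

## What the generator does and does not emulate

It emulates sampling noise in event counts, between-study variation in
baseline risk, and confounding by a single continuous covariate with a
common linear effect on the log-odds scale. It does not emulate: multiple
or binary covariates, design-specific true effects (theta₁ ≠ theta₂),
unequal arm sizes, other internal biases (performance, attrition), or
reporting artefacts. Passing tests therefore demonstrate that the adjusted
model removes *linear single-covariate imbalance bias* under an otherwise
correctly specified likelihood — not that it fixes observational evidence
in general.

## The four synthesis models

Shared likelihood: r ~ Binomial(n, p) per arm with logit(p_C) = gamma and
logit(p_T) = gamma + psi. Priors: gamma ~ N(0, 1000); overall effect
mu ~ N(0, 10); random-effects SDs sigma_i, tau ~ half-normal obtained by
truncating N(0, 0.26) to (0, ∞) ("0.26" is the pre-truncation *variance*,
i.e. SD ≈ 0.51 — the conventional weakly informative choice that permits
near-equality of studies while discounting extreme heterogeneity);
imbalance coefficient alpha ~ N(0, 1000).

* **Unadjusted (I)** — psi_ij ~ N(theta_i, sigma_i²), theta_i ~ N(mu, tau²).
* **Difference-adjusted (II)** — mean theta_i + alpha·(x_T − x_C). A single
  alpha is shared by all studies of both types; randomised studies have
  zero difference, so they anchor the theta_i while the non-randomised
  contrasts identify alpha.
* **Aggregate-adjusted (III)** — mean theta_i + alpha·x̄, where x̄ is the
  unweighted mean of the two arm means, centred at the grand mean across
  studies. The aggregation rule and centring are our choices (arm-size
  weighting would be an alternative): centring aids sampler identifiability
  and shifts only the theta intercepts, never the pooled contrast. A
  study-level mean cannot see *within*-study imbalance, which is exactly why
  this model fails in the simulations.
* **Informative prior (IV)** — two stages. Stage 1 fits the two-level
  random-effects model (psi ~ N(mu, sigma²), mu ~ N(0, 10), sigma
  half-normal) separately to the non-randomised studies (keeping the
  posterior *median* m_N, consistent with the median-based scoring) and to
  the randomised studies (keeping the posterior *variance* v_R; the
  posterior variance is our reading of "the variance of the RCTs" — a
  frequentist pooled variance would be the alternative). Stage 2 fits the
  two-level model to the randomised studies only with mu ~ N(m_N, c·v_R).
  The inflation factor c (default 4) controls downweighting; c → ∞
  recovers the RCT-only posterior (property-tested), c = 1 treats the
  non-randomised pooled estimate as exchangeable with the RCT evidence.

Every specification exposes its joint log density, which the tests verify
against an independent term-by-term summation oracle at random parameter
points; the difference-adjusted model with alpha = 0 is density-identical
to the unadjusted model.

## Inference

Sampling is Metropolis-within-Gibbs, chosen to match the models' conditional
structure:

* theta_i, mu and alpha have normal full conditionals — exact Gibbs draws;
* gamma_ij and psi_ij have full conditionals that factor across studies —
  vectorised per-study Gaussian random-walk Metropolis, one accept/reject
  per study;
* sigma_i and tau are updated by random-walk Metropolis on the log scale
  (Jacobian included), with the half-normal prior evaluated on the positive
  domain — no reflection tricks.

Proposal scales adapt toward ~44% acceptance in windows of 50 iterations
during burn-in only (so the post-burn-in kernel is fixed and valid).
Initial values: empirical logits with a 0.5 continuity correction for gamma,
empirical log odds ratios for psi, the prior median for the SDs, zero for
mu/theta/alpha, all jittered per chain; if the likelihood is non-finite at
initialisation the jitter is redrawn up to 5 times before failing loudly.
Initialisation is a convenience, not a correctness claim — convergence is
asserted by diagnostics, not by iteration counts.

Two chains are run by default and summaries pool the thinned draws of both
chains; the potential scale reduction factor (PSRF, the between/within-chain
variance ratio, floored at 1) is reported per parameter. The sampler is
cross-checked in the test suite against (a) an independent ensemble sampler
on the same log density, (b) a large-count conjugate approximation, and
(c) reduced-scale simulation-based calibration (uniform rank statistics of
the true mu under prior-predictive resimulation).

Profiles. The **full** profile is 50k burn-in + 10k iterations thinned by
20, per chain (1000 retained draws total). The **reduced** profile — the
package default for the study harness and tests — keeps the same 1000
retained draws but uses 3k burn-in + 5k iterations thinned by 10, which this
sampler's diagnostics support on the built-in scenarios. For the 40-NRS
scenarios the harness runs the three-level models 4× longer (burn-in and
sampling phase, thinning scaled so the retained count is unchanged):
with 40 imbalanced studies the SD levels sit in strong prior-data conflict
and alpha is coupled to 40 study effects, so autocorrelation is much higher.
Fits whose PSRF for mu (or alpha) exceeds 1.1 are excluded from the
performance summaries and reported, never silently dropped — exclusion
keeps the estimand clean, at the cost of a (reported) reduction in
replicates.

Everything is vectorised over a batch axis: the two chains of one fit, and
in the harness all replicate datasets of a scenario, advance through the
sampler simultaneously as independent states. Batching changes runtime
only, not the target distribution; but `fit()` on a single dataset and a
batched `run_study()` consume random numbers in different orders, so their
draws differ (each is individually deterministic given its seed).

## Performance criteria

For each model × scenario: mean over replicates of the per-replicate
posterior median of mu; its standard error (SD of the medians / √S); bias
(mean minus the true −0.20); and Z = bias / SE, with |Z| ≤ 1.96 read as
"no detectable bias". These are exact arithmetic identities of the stored
medians (tested as such). Supporting checks: recovery of alpha by the
difference-adjusted model (across-replicate mean of alpha's posterior
medians ≈ 0.10 / ≈ 0.52 under the weak/strong-imbalance scenarios), and a
two-seed stability report for the differences in mean treatment effect of
models I/III/IV relative to model II. Because all models fit the same
replicate datasets, the SE of such a difference is computed from the
*paired* per-replicate differences. The forest-style plot shows mean
± 1.96·SE of the mean median (a sampling interval for the mean, not a
percentile interval across replicates — the other reasonable reading).

## Problem sizes

The harness defaults to desk-scale runs: the reduced MCMC profile with 100
replicates for the 8-study scenarios and 30 for the 44-study ones in the
reproduction script, and 30 replicates in the acceptance tests. At these
sizes the whole suite runs in a couple of minutes on one CPU; Monte-Carlo
error of a scenario's mean median is then ≈ 0.02–0.12 log-OR units
depending on the model and scenario, and tolerances in the tests are stated
in multiples of the SE estimated from the run itself.

## Known limitations

* Single covariate, linear on the log-odds scale, common alpha across
  designs; the interface keeps the covariate generic but M > 1 is not
  implemented.
* The 40-NRS unadjusted/aggregate posteriors are deliberately misspecified
  (within-type SD wants to exceed what the half-normal prior supports);
  their chains mix slowly, which is why the harness lengthens them and
  screens by PSRF.
* Model IV's two-stage construction is not a coherent joint model (the
  prior is estimated from data); it is implemented as the downweighting
  recipe it is.
* Percentile-based interval summaries require enough retained draws; the
  defaults keep 1000 across chains, so extreme-tail summaries are coarse.
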