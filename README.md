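# hiersynth

Bayesian hierarchical synthesis of randomised and non-randomised two-arm
binomial studies, with adjustment for covariate imbalances between study
arms — plus the simulation-study harness that quantifies how badly things
go when you don't adjust.

## The problem

Health-care decisions often need *all* the comparative evidence on a
treatment: a handful of randomised controlled trials (RCTs) and a set of
larger non-randomised (observational) studies. Three-level Bayesian
hierarchical models pool both: study log odds ratios ψᵢⱼ are drawn around
design-type effects θᵢ, which are drawn around an overall population effect
μ. But non-randomised studies are prone to imbalances between their arms in
prognostic covariates (here: mean patient age), which confound the
treatment effect and bias the pooled estimate.

## The models

All models share the binomial likelihood, for study *j* of design type *i*
(i = 1 randomised, 2 non-randomised):

    r_Cij ~ Binomial(p_Cij, n_Cij)      logit(p_Cij) = γ_ij
    r_Tij ~ Binomial(p_Tij, n_Tij)      logit(p_Tij) = γ_ij + ψ_ij

and differ in the mean structure on the study log odds ratio ψᵢⱼ:

| model | mean of ψᵢⱼ | idea |
|---|---|---|
| unadjusted (I) | θᵢ | plain three-level pooling |
| difference-adjusted (II) | θᵢ + α·(x_Tij − x_Cij) | within-study arm imbalance absorbed by α |
| aggregate-adjusted (III) | θᵢ + α·x̄ᵢⱼ | meta-regression on the study-level covariate mean |
| informative prior (IV) | two-level, RCTs only | NRS evidence enters as a variance-inflated prior on μ |

Models I–III close with ψᵢⱼ ~ N(·, σᵢ²), θᵢ ~ N(μ, τ²), μ ~ N(0, 10),
half-normal priors (pre-truncation variance 0.26) on σᵢ and τ, and
N(0, 1000) priors on the γᵢⱼ and on α. Model IV fits a simple random-effects
model to the RCTs with μ ~ N(m_N, c·v_R), where m_N is the pooled
non-randomised posterior median, v_R the pooled RCT posterior variance, and
c (default 4) the variance-inflation / downweighting factor.

Fitting is by Markov chain Monte Carlo: a Metropolis-within-Gibbs sampler
with exact conjugate draws for θᵢ, μ and α, vectorised per-study
random-walk updates for γ and ψ, and log-scale random-walk updates for the
standard deviations, run as two diagnostic chains with between/within-chain
PSRF convergence checks.

The simulation harness generates scenario-controlled datasets in which
imbalance exists *only* in the non-randomised studies (ages
x_T ~ U(75, 90) vs x_C ~ U(70, 85), so +5 years on average; RCT arms share
one age), with a true overall log odds ratio of −0.20, control-arm risks
Beta(mean 0.04, var 0.001) and ψᵢⱼ = θ + α·(x_T − x_C). Each model is
scored by bias — the mean over replicate datasets of the posterior median
of μ, minus the truth — and by Z = bias / SE.

## Worked example

```python
from hiersynth import (get_scenario, simulate_dataset,
                       DifferenceAdjustedSynthesis, UnadjustedSynthesis)

dataset = simulate_dataset(get_scenario(1), rng_seed=42)   # 4 RCT + 4 NRS
adj   = DifferenceAdjustedSynthesis(random_state=0).fit(dataset.to_frame())
unadj = UnadjustedSynthesis(random_state=0).fit(dataset.to_frame())
print(adj.mu_median_, adj.mu_interval_, adj.alpha_median_, adj.odds_ratio_())
print(unadj.mu_median_, unadj.odds_ratio_())
```

prints (rounded)

```
adjusted   mu median -0.171  95% (-0.908, 0.586)  alpha 0.049  OR 0.843
unadjusted mu median -0.096                                    OR 0.908
```

On this single dataset the adjusted posterior median sits near the true
−0.20 (odds ratio 0.82) while the unadjusted one is pulled toward zero by
the age-confounded non-randomised studies; α's posterior median is the
model's estimate of the imbalance impact per year of age difference. One
dataset is noisy — the repeated-simulation harness is where the pattern
becomes unambiguous:

```python
from hiersynth import run_study, performance_table, McmcSettings
results = run_study(1, models=("I", "II"), n_simulations=30, master_seed=1,
                    settings=McmcSettings.reduced())
print(performance_table(results, true_theta=-0.20))
```

```
 scenario         model  mean_median_logOR  se_mean_median   bias  z_statistic  unbiased
        1  unadjusted_I             0.0854          0.0463 0.2854       6.1699     False
        1 difference_II            -0.1929          0.0390 0.0071       0.1818      True
```

The unadjusted model is biased by ≈ +0.29 (|Z| ≫ 1.96, and on the wrong
side of zero — it calls a beneficial treatment harmful); the
difference-adjusted model is statistically indistinguishable from the truth.

The same study runs from the shell:

```
hiersynth scenarios                                   # print the 6 built-in scenarios
hiersynth simulate --scenario 1 --n 5 --seed 7        # write dataset CSVs
hiersynth fit --data datasets/dataset_000.csv --models I,II
hiersynth study --scenario 1 --models I,II,III,IV --n 30 --seed 1 --stability
```

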