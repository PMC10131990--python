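# crc3s — three-source capture-recapture population size estimation

`crc3s` estimates the size of hidden populations — groups with no
sampling frame, such as key populations in HIV surveillance — from the
overlaps between multiple "capture" rounds. It implements the
three-source capture-recapture (3S-CRC) workflow used in national key
population size estimation studies: capture-history tables, a Bayesian
nonparametric latent-class capture-recapture model, classical
closed-form estimators, respondent-driven-sampling (RDS) dependency
diagnostics, survey sample-size calculators, and synthetic data
generators. It ships the published aggregate data of the 2021 Rwanda
national MSM study as a worked reproduction.

## The model

A closed population of unknown size *N* is sampled on *k* occasions.
Each individual's capture history **x** ∈ {0,1}^k is observed unless it
is all zeros; the 2^k − 1 observable histories form a contingency table
and the all-zero count *n₀* is the estimand (*N* = *n* + *n₀*).

Real populations are heterogeneous, which induces dependence between
occasions and biases homogeneous estimators. The latent-class model
treats the population as a mixture: individual *i* belongs to an
unobserved class *z_i* with class- and occasion-specific capture
probabilities λ_jk, so

  P(**x**) = Σ_k π_k Π_j λ_jk^{x_j} (1 − λ_jk)^{1−x_j},

with stick-breaking (Dirichlet-process) weights π, V_k ~ Beta(1, α),
α ~ Gamma(a, b) (default 0.25, 0.25), λ_jk ~ Beta(1, 1), and the
scale-invariant prior p(N) ∝ 1/N handled by negative-binomial
augmentation of *n₀*. Inference is by Gibbs sampling; the population
size is summarised by the posterior median and a 95% highest-density
credible set.

## Worked example

```python
from crc3s import LCMCRConfig, fit_lcmcr
from crc3s.datasets import rwanda_reproduction_tables

strata, national = rwanda_reproduction_tables()
cfg = LCMCRConfig(k_star=5, n_samples=2000, burn_in=10_000, thinning=25, seed=1)
fit = fit_lcmcr(national, cfg)
print(f"posterior median N = {fit.median_N:,.0f}")
print(f"95% HDI = ({fit.cs_lower:,.0f}, {fit.cs_upper:,.0f})")
```

prints

```
posterior median N = 15,362
95% HDI = (9,468, 23,130)
```

— the estimated national adult MSM population: the point estimate is the
posterior median of *N*, and the interval is the shortest set holding
95% posterior probability (a single desk-scale chain; medians in the
14,000–20,000 range are typical across seeds at these settings, see
`docs/methods.md` on mixing). Stratum tables fit the same way; the
Eastern province table, for example, gives a median of 2,289 (95% HDI
1,830–2,869) under the same settings.

The `examples/` directory holds one short script per capability: table
construction, model fitting, sample-size calculation, homophily
diagnostics, and power simulation. A thin CLI wraps the pipeline:

```bash
crc3s build-tables --input marginals.csv --out tables.csv
crc3s fit --input marginals.csv --out fit.json --seed 1
crc3s design --config design.yaml --out sizes.csv
```

## Two tabulation conventions (important)

`table_from_marginals` builds the person-level 7-cell table from
published marginals by inclusion-exclusion — the statistically correct
aggregation, and the default everywhere. `table_from_marginals_direct`
instead assigns each printed count to its own pattern cell without
overlap correction. The bundled Rwanda study's published estimates are
reproduced by the *direct* tabulation, not by the inclusion-exclusion
tables; `docs/methods.md` documents the evidence. Use the default for
new data.

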