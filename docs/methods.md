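# Methods

## Model

The population of unknown size N is closed over the study window. Each
member carries a latent class z ∈ {1, …, K\*}; given z = k, captures on
the J occasions are independent Bernoulli(λ_jk). Class weights follow a
truncated stick-breaking construction π_k = V_k Π_{l<k}(1 − V_l) with
V_k ~ Beta(1, α) for k < K\* and V_{K\*} = 1; the concentration α has a
Gamma(a_α, b_α) hyperprior (default shape 0.25, rate 0.25), so the
effective number of classes adapts to the data within the truncation.
Capture probabilities have independent Beta(1, 1) priors. The number of
never-captured individuals n₀ is given the scale-invariant prior
p(N) ∝ 1/N, equivalently the negative-binomial full conditional
P(n₀ = m) ∝ C(n + m − 1, m) (1 − p₀)^n p₀^m, where
p₀ = Σ_k π_k Π_j (1 − λ_jk) is the probability of an all-zero history.

## Sampler

One Gibbs sweep updates, in order: (1) n₀ from its negative binomial,
drawn through the Gamma–Poisson mixture so large counts cannot
overflow; (2) latent-class allocations, collapsed to one multinomial per
distinct observed pattern plus one for the n₀ augmented zero-histories —
given (π, λ) individual allocations are conditionally independent, so
this is exact and far cheaper than per-individual sampling; (3) each
λ_jk from its conjugate Beta, counting augmented individuals as
non-captures on every occasion; (4) the stick fractions V_k from
Beta(1 + m_k, α + Σ_{l>k} m_l); (5) α from
Gamma(a_α + K\* − 1, b_α − Σ_{k<K\*} log(1 − V_k)). V and λ are clipped
to [1e−12, 1 − 1e−12]; a non-finite state raises with the iteration
index. Total iterations are burn_in + n_samples × thinning, keeping
every thinning-th sweep after burn-in. Identical seeds give bit-identical
draws; per-stratum fits derive child seeds from one `SeedSequence`.

The sampler is validated against independent oracles rather than a
reference implementation: at K\* = 1 the class structure vanishes and
the posterior of N can be computed by brute force (conjugate Beta
integrals over a grid of N, including the 1/N prior); the Gibbs median
matches it to well under 1%. The K\* = 1 fit also matches the Chapman
estimator on two-occasion data and the profile-likelihood independence
MLE on three-occasion data within stochastic tolerance, and a from-
scratch marginal Metropolis sampler (augmentation integrated out
analytically, conditional multinomial likelihood) reproduces the same
posterior on real tables.

## Credible sets

The 95% highest-density interval is the shortest window of the sorted
draws containing ⌈0.95 n⌉ order statistics; on ties the window with the
smallest lower bound is returned. Equal-tail intervals are plain
quantiles. At least 100 draws are required.

## Mixing and run lengths

The posterior of N is heavy-tailed and, for strongly dependent tables,
effectively bimodal between low-heterogeneity (small N) and
high-heterogeneity (large N) configurations, so single short chains can
misplace the median by 10–20%. The reproduction script therefore pools
several independently seeded chains of moderate length (six chains of
10,000 burn-in plus 25,000 kept-region sweeps each) rather than one
long chain; at these settings stratum medians are stable to a few
percent across master seeds. Library defaults
(n_samples 10,000 / burn-in 10,000 / thinning 1,000) mirror the field
convention for production runs; desk-scale analyses should scale
thinning down and pool chains instead.

## Tabulation conventions and the bundled reproduction

`table_from_marginals` recovers the seven person-level cells from
published totals/overlaps by inclusion-exclusion, with a strict policy
(raise on a negative cell) and a clamp policy (truncate at zero, attach
a warning). The bundled Western-province marginals are mutually
inconsistent (the services-only cell computes to −17), so the
reproduction pipeline clamps and logs.

Fitting the latent-class model to these inclusion-exclusion tables does
**not** reproduce the bundled study's published estimates: the national
posterior median sits near 6,900 against a published 18,100, a finding
confirmed by two independent samplers, long runs from overdispersed
starts, and prior-sensitivity checks (truncation 5–20, flat vs 1/N
prior on N, fixed vs hyperprior concentration, Beta(0.25, 0.25) capture
priors). Assigning each printed marginal count directly to its own
pattern cell — occasion totals as single-capture cells, overlaps
uncorrected, implemented as `table_from_marginals_direct` — reproduces
all published stratum estimates closely (long-run medians: Eastern
2,286 vs 2,287; Southern 2,114 vs 2,109; Northern 2,265 vs 2,375;
Western 2,440 vs 2,469; Kigali 7,028–7,276 vs 7,842) and places the
national estimate in the published credible region (equilibrium median
≈ 15,200 vs published 18,100, with published bounds 11,300–29,700
bracketing our HDI). The original analysis therefore appears to have
tabulated each published summary count as its own capture-history row,
double-counting recaptures. The direct tabulation is retained, clearly
labelled and warning-attached, for reproduction; the inclusion-
exclusion construction is the default and the correct choice for new
data. The residual national gap (ours ≈ 15,200 vs 18,100) is consistent
with a single slowly mixing chain having sat in the upper region of its
posterior; no defensible model variant we tested moves the equilibrium
median to 18,100.

## Classical comparators

Chapman: N̂ = (n₁+1)(n₂+1)/(m+1) − 1 with the standard variance and a
lognormal-style CI; finite at m = 0 and bounded above by
Lincoln–Petersen for m ≥ 1. The three-list independence MLE profiles
p_j = n_j/N out of the multinomial likelihood and maximises over N by
bounded one-dimensional search on [n, 100n]. These are diagnostics and
oracles, not production estimators.

## RDS diagnostics

Recruitment homophily on an attribute (e.g. prior-capture status):
observed same-value recruiter→recruit edges divided by the
random-mixing expectation n_edges · Σ_g s_g², where s_g are the
attribute shares among recruits. H = 1 under random mixing; H > 1
signals recruitment follows the attribute, threatening the independence
of an RDS capture round. Seeds recruit but are never recruits. The
Geweke stationarity z-score compares the means of the first 10% and
last 50% of a chain with AR-based spectral density estimates at
frequency zero (order chosen by AIC); short segments fall back to the
sample variance. Trace/histogram exports use Freedman–Diaconis binning
with a single-bin fallback for constant chains.

## Sample-size calculators

Both the RDS survey and the capture rounds use
n = deff · z² · p(1 − p) / w², inflated by 1/(1 − adjust) for
nonresponse or coupon loss, rounded half-up by default (ceiling
available). With the bundled stratum prevalences (11.3%, 6.4%, 1.4%,
3.1%, 1.2%), deff 1.5, w 0.025, z 1.96 and 10% nonresponse this gives
1027, 614, 141, 308, 121; the published 613 for the second stratum
corresponds to truncation of 613.67 rather than rounding. The published
capture-round sizes are not recovered exactly by the stated formula
(e.g. 811 computed vs 803 printed for the largest stratum); the exact
convention is not recoverable from the published description, so these
are not asserted.

## Synthetic data

`simulate_captures` draws a class per individual and independent
Bernoulli captures per occasion, then drops all-zero histories — the
exact generative twin of the fitted model under closure (no entry/exit
between rounds). It does not emulate misreporting of prior captures or
object loss, which the Western inconsistency suggests exist in real
data; passing recovery tests therefore validate the inference machinery,
not robustness to measurement error. `simulate_chain` grows a coupon
branching forest (default 24 seeds, 3 coupons) in which a recruit copies
the recruiter's group with probability h, else draws from the group
shares, so h = 0 is random mixing (homophily ≈ 1) and h = 1 perfect
assortativity.

## Parameter-recovery properties and their limits

Credible-set coverage is checked over 40 simulated replicates of a
two-class population (N = 10,000; class profiles (0.65, 0.60, 0.55) and
(0.40, 0.35, 0.45), weights 0.4/0.6), where observed coverage at
desk-scale settings is ~92%. Coverage degrades for designs containing a
large, weakly captured class (per-occasion probabilities ≲ 0.1): the
stick-breaking prior shrinks toward fewer classes, the posterior median
sits a few percent low and the nominal 95% sets under-cover (~75–85% in
our experiments). This is a property of the model and priors at such
designs, not of the implementation, and it is the regime in which
population-size estimates from real 3S-CRC data should be read with the
most caution.
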