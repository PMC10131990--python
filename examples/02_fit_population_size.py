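"""Fit the Bayesian nonparametric latent-class model to a capture table.

The model mixes latent classes with class-specific capture
probabilities under a Dirichlet-process prior, augments the
never-captured count, and reports the posterior median of the
population size N with a 95% highest-density credible set.
"""

from crc3s import LCMCRConfig, fit_lcmcr
from crc3s.datasets import rwanda_reproduction_tables

strata, national = rwanda_reproduction_tables()
cfg = LCMCRConfig(k_star=5, n_samples=2000, burn_in=10_000, thinning=25, seed=1)

fit = fit_lcmcr(national, cfg)
print(f"national: observed {fit.n_observed} men in at least one round")
print(f"posterior median N = {fit.median_N:,.0f}")
print(f"95% HDI = ({fit.cs_lower:,.0f}, {fit.cs_upper:,.0f})")
# The median is the point estimate of the total MSM population aged 18+;
# the interval reflects both sampling noise and heterogeneity uncertainty.

eastern = next(t for t in strata if t.stratum == "Eastern")
fit_e = fit_lcmcr(eastern, cfg)
print(f"Eastern: median N = {fit_e.median_N:,.0f} "
      f"(95% HDI {fit_e.cs_lower:,.0f}-{fit_e.cs_upper:,.0f})")
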