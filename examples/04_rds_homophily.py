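"""Check capture-RDS dependence via recruitment homophily.

Capture-recapture assumes the RDS round recruits independently of prior
capture status. The homophily ratio compares same-group recruitments to
the random-mixing expectation; 1 means no dependence.
"""

from crc3s import ChainScenario, recruitment_homophily, simulate_chain

random_mixing = simulate_chain(
    ChainScenario(n_seeds=24, coupons=3, target_size=4000, h=0.0, seed=2), attribute="g"
)
h0 = recruitment_homophily(random_mixing, "g")
print(f"random mixing:   H = {h0.ratio:.3f} ({h0.observed:.0f} same-group of {h0.n_edges} edges)")

assortative = simulate_chain(
    ChainScenario(n_seeds=24, coupons=3, target_size=4000, h=0.6, seed=2), attribute="g"
)
h1 = recruitment_homophily(assortative, "g")
print(f"assortative:     H = {h1.ratio:.3f}")
# H near 1 supports treating the RDS round as an independent capture;
# H substantially above 1 signals recruitment follows the attribute.
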