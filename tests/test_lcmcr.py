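"""Latent-class capture-recapture sampler and posterior summaries."""

import numpy as np
import pytest
from scipy.special import betaln, gammaln

from crc3s.capture_histories import CaptureHistoryTable
from crc3s.classical import chapman, independence_mle_3list
from crc3s.lcmcr import LCMCRConfig, credible_set, fit_all_strata, fit_lcmcr
from crc3s.synthetic import PopulationScenario, simulate_captures

FAST = LCMCRConfig(k_star=3, n_samples=500, burn_in=500, thinning=2, seed=0)


class TestCredibleSet:
    def test_equal_tail_uniform_order_statistics(self):
        draws = np.arange(1, 101)
        lo, hi = credible_set(draws, 0.95, "equal_tail")
        assert lo == pytest.approx(np.quantile(draws, 0.025))
        assert hi == pytest.approx(np.quantile(draws, 0.975))

    def test_hdi_matches_equal_tail_for_symmetric_draws(self):
        draws = np.random.default_rng(0).normal(size=20_000)
        lo_h, hi_h = credible_set(draws, 0.9, "hdi")
        lo_e, hi_e = credible_set(draws, 0.9, "equal_tail")
        assert lo_h == pytest.approx(lo_e, abs=0.08)
        assert hi_h == pytest.approx(hi_e, abs=0.08)

    def test_hdi_shorter_than_equal_tail_for_skewed_draws(self):
        draws = np.random.default_rng(1).exponential(size=5000)
        lo_h, hi_h = credible_set(draws, 0.95, "hdi")
        lo_e, hi_e = credible_set(draws, 0.95, "equal_tail")
        assert hi_h < hi_e
        assert (hi_h - lo_h) <= (hi_e - lo_e)

    def test_hdi_matches_brute_force_shortest_window(self):
        draws = np.sort(np.random.default_rng(2).gamma(2.0, size=500))
        m = int(np.ceil(0.9 * 500))
        widths = [draws[i + m - 1] - draws[i] for i in range(500 - m + 1)]
        i_best = int(np.argmin(widths))
        lo, hi = credible_set(draws, 0.9, "hdi")
        assert (lo, hi) == (draws[i_best], draws[i_best + m - 1])

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            credible_set(np.arange(50), 0.95)


def exact_homogeneous_posterior_median(table):
    """Brute-force posterior median of N for the one-class model.

    Marginalises the capture probabilities (conjugate Beta integrals) and
    the scale-invariant 1/N prior over a grid of N.
    """
    n = table.n_observed
    nj = [table.occasion_total(j) for j in range(table.k)]
    Ns = np.arange(n, 60 * n)
    logp = gammaln(Ns + 1) - gammaln(Ns - n + 1) - np.log(Ns)
    for v in nj:
        logp = logp + betaln(1 + v, 1 + Ns - v)
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p) / p.sum()
    return float(Ns[np.searchsorted(cdf, 0.5)])


class TestFitLcmcr:
    def test_single_class_matches_exact_posterior(self):
        cells = {"111": 5, "110": 12, "101": 8, "011": 10, "100": 30, "010": 25, "001": 28}
        t = CaptureHistoryTable(3, cells)
        cfg = LCMCRConfig(k_star=1, n_samples=4000, burn_in=2000, thinning=5, seed=3)
        s = fit_lcmcr(t, cfg)
        assert s.median_N == pytest.approx(exact_homogeneous_posterior_median(t), rel=0.03)

    def test_degenerate_all_captured(self):
        cells = {p: 0 for p in ("100", "010", "001", "110", "101", "011")}
        cells["111"] = 500
        s = fit_lcmcr(CaptureHistoryTable(3, cells), FAST)
        assert s.median_N == 500
        assert np.median(s.draws_p0) < 0.01

    def test_single_class_agrees_with_chapman_on_two_occasion_data(self):
        table, _ = simulate_captures(PopulationScenario(N=2000, lam=(0.4, 0.4), seed=4))
        m = table.cells["11"] + 0
        n1 = table.occasion_total(0)
        n2 = table.occasion_total(1)
        cfg = LCMCRConfig(k_star=1, n_samples=1000, burn_in=1000, thinning=2, seed=4)
        s = fit_lcmcr(table, cfg)
        assert s.median_N == pytest.approx(chapman(n1, n2, m).estimate, rel=0.10)

    def test_single_class_agrees_with_independence_mle(self):
        table, _ = simulate_captures(PopulationScenario(N=5000, lam=(0.3, 0.25, 0.35), seed=5))
        cfg = LCMCRConfig(k_star=1, n_samples=1000, burn_in=1000, thinning=2, seed=5)
        s = fit_lcmcr(table, cfg)
        assert s.median_N == pytest.approx(independence_mle_3list(table), rel=0.10)

    def test_posterior_invariants(self, eastern_table):
        s = fit_lcmcr(eastern_table, FAST)
        assert np.all(s.draws_N >= eastern_table.n_observed)
        assert np.all((s.draws_p0 > 0) & (s.draws_p0 < 1))
        assert np.all(s.draws_alpha > 0)
        assert s.cs_lower <= s.median_N <= s.cs_upper

    def test_seeded_bit_reproducibility(self, eastern_table):
        a = fit_lcmcr(eastern_table, FAST)
        b = fit_lcmcr(eastern_table, FAST)
        assert np.array_equal(a.draws_N, b.draws_N)
        assert np.array_equal(a.draws_alpha, b.draws_alpha)

    def test_occasion_permutation_of_symmetric_table_is_invariant(self):
        # table symmetric under swapping occasions 1 and 2
        cells = {"100": 50, "010": 50, "001": 80, "110": 20, "101": 15, "011": 15, "111": 10}
        t = CaptureHistoryTable(3, cells)
        tp = t.permute_occasions([1, 0, 2])
        assert tp.cells == t.cells
        a = fit_lcmcr(t, FAST)
        b = fit_lcmcr(tp, FAST)
        assert np.array_equal(a.draws_N, b.draws_N)

    def test_unidentifiable_table_warns(self):
        cells = {"100": 5, "010": 5, "001": 5, "110": 0, "101": 0, "011": 0, "111": 0}
        with pytest.warns(UserWarning, match="identifiable"):
            fit_lcmcr(CaptureHistoryTable(3, cells), FAST)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LCMCRConfig(k_star=0)
        with pytest.raises(ValueError):
            LCMCRConfig(cs_level=1.5)
        with pytest.raises(ValueError):
            LCMCRConfig(cs_method="mode")


class TestFitAllStrata:
    def test_per_stratum_fits_are_labelled_and_deterministic(self, eastern_table, national_table):
        cfg = LCMCRConfig(k_star=2, n_samples=200, burn_in=200, thinning=1, seed=11)
        out = fit_all_strata([eastern_table, national_table], cfg)
        assert set(out) == {"Eastern", "national"}
        again = fit_all_strata([eastern_table, national_table], cfg)
        assert np.array_equal(out["Eastern"].draws_N, again["Eastern"].draws_N)

    def test_empty_list(self):
        assert fit_all_strata([], FAST) == {}
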