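"""Allele counting, real-time tracking, enrichment, Monte Carlo TF estimation."""

import numpy as np
import pytest
from scipy import stats

from rcakit import synth
from rcakit.snv import (
    AlleleCounts,
    count_alleles,
    cumulative_mut_ratio,
    estimate_tf_snv,
    fisher_mut_enrichment,
    marginal_mut_probability,
    mut_probability,
    simulate_mut_counts,
)
from rcakit.synth import AlleleObservations


def obs_from_calls(calls, timestamps=None, n_sites=10):
    calls = np.asarray(calls, dtype="U3")
    ts = np.asarray(timestamps, dtype=float) if timestamps is not None else np.arange(len(calls), dtype=float)
    return AlleleObservations(
        site_index=np.zeros(len(calls), dtype=np.int64), call=calls, timestamp=ts, n_sites=n_sites
    )


class TestCountAlleles:
    def test_empty(self, small_panel):
        obs = AlleleObservations(
            site_index=np.array([], dtype=np.int64),
            call=np.array([], dtype="U3"),
            timestamp=np.array([]),
            n_sites=small_panel.n_sites,
        )
        assert count_alleles(obs, small_panel) == AlleleCounts(0, 0, 0)

    def test_direct_tally(self, small_panel):
        obs = obs_from_calls(["REF"] * 10 + ["MUT"] * 3 + ["ERR"], n_sites=small_panel.n_sites)
        assert count_alleles(obs, small_panel) == AlleleCounts(10, 3, 1)

    def test_generator_closed_form(self):
        panel = synth.generate_variant_panel(100, vaf_mean=0.5, vaf_sd=0.0, purity=1.0, seed=0)
        obs = synth.generate_allele_observations(panel, tf=0.5, coverage=1000, seed=1)
        c = count_alleles(obs, panel)
        sd = np.sqrt(0.25 * 0.75 / c.n_obs)
        assert abs(c.n_mut / c.n_obs - 0.25) <= 3 * sd

    def test_panel_mismatch(self, small_panel, uniform_panel):
        obs = obs_from_calls(["REF"], n_sites=small_panel.n_sites)
        with pytest.raises(ValueError):
            count_alleles(obs, uniform_panel)


class TestCumulativeMutRatio:
    def test_all_ref_flat_zero(self):
        obs = obs_from_calls(["REF"] * 20, timestamps=np.linspace(0, 99, 20))
        out = cumulative_mut_ratio(obs, bin_minutes=10)
        assert np.all(out["cum_mut_ratio"].to_numpy() == 0.0)

    def test_two_mut_then_two_ref(self):
        obs = obs_from_calls(["MUT", "MUT", "REF", "REF"], timestamps=[2.0, 5.0, 12.0, 15.0])
        out = cumulative_mut_ratio(obs, bin_minutes=10)
        assert out["cum_mut_ratio"].tolist() == [1.0, 0.5]

    def test_empty_bins_carry_forward(self):
        obs = obs_from_calls(["MUT"], timestamps=[1.0])
        out = cumulative_mut_ratio(obs, bin_minutes=10, total_minutes=40)
        assert out["cum_mut_ratio"].tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_tumor_stream_exceeds_healthy(self, small_panel):
        common = dict(coverage=100, error_rate=0.00072, run_minutes=180.0)
        tumor = synth.generate_allele_observations(small_panel, tf=0.3, seed=2, **common)
        healthy = synth.generate_allele_observations(small_panel, tf=0.0, seed=3, **common)
        rt = cumulative_mut_ratio(tumor, bin_minutes=10, total_minutes=180)
        rh = cumulative_mut_ratio(healthy, bin_minutes=10, total_minutes=180)
        after_20 = rt["minutes"] > 20
        assert np.all(
            rt.loc[after_20, "cum_mut_ratio"].to_numpy()
            > rh.loc[after_20, "cum_mut_ratio"].to_numpy()
        )


class TestFisher:
    def test_identical_tables_not_enriched(self):
        # One-sided p for identical tables includes the observed table's
        # own probability, so it sits above 0.5 rather than at exactly 1.
        assert fisher_mut_enrichment(AlleleCounts(50, 50, 0), AlleleCounts(50, 50, 0)) > 0.5

    def test_strong_enrichment_matches_hypergeometric_tail(self):
        p = fisher_mut_enrichment(AlleleCounts(50, 50, 0), AlleleCounts(100, 0, 0))
        # One-sided Fisher p = hypergeometric tail P(X >= 50).
        oracle = stats.hypergeom.sf(49, 200, 50, 100)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 1e-9

    def test_no_mut_anywhere(self):
        assert fisher_mut_enrichment(AlleleCounts(100, 0, 0), AlleleCounts(100, 0, 0)) == 1.0

    def test_degenerate_warns(self):
        with pytest.warns(UserWarning):
            assert fisher_mut_enrichment(AlleleCounts(0, 0, 0), AlleleCounts(0, 0, 0)) == 1.0


class TestMutProbability:
    @pytest.mark.parametrize(
        "purity,vaf,p", [(0.6, 0.5, 0.30), (1.0, 0.42, 0.42), (0.8, 0.25, 0.20)]
    )
    def test_product_rule(self, purity, vaf, p):
        assert mut_probability(purity, vaf) == pytest.approx(p)

    def test_validation(self):
        for bad in ((0.0, 0.5), (0.5, 0.0), (1.2, 0.5), (0.5, 1.2)):
            with pytest.raises(ValueError):
                mut_probability(*bad)


class TestSimulateMutCounts:
    def test_null_all_zero(self, small_panel):
        counts = simulate_mut_counts(small_panel, 500, tf=0.0, error_rate=0.0, seed=4)
        assert np.all(counts == 0)

    def test_single_probability_mean(self):
        panel = synth.generate_variant_panel(1, vaf_mean=0.5, vaf_sd=0.0, purity=0.6, seed=5)
        counts = simulate_mut_counts(panel, 1000, tf=1.0, n_trials=5000, seed=6)
        sd = np.sqrt(1000 * 0.3 * 0.7) / np.sqrt(5000)
        assert abs(counts.mean() - 300) <= 3 * sd

    def test_matches_binomial_chi_square(self, uniform_panel):
        # All sites share P = 0.5; tf = 0.5 -> Binomial(400, tf*P = 0.25).
        counts = simulate_mut_counts(uniform_panel, 400, tf=0.5, n_trials=10_000, seed=7)
        kmax = counts.max()
        observed = np.bincount(counts, minlength=kmax + 1)
        expected = 10_000 * stats.binom.pmf(np.arange(kmax + 1), 400, 0.25)
        # Pool tails so expected cell counts stay above 5.
        lo = np.searchsorted(np.cumsum(expected), 5.0)
        hi = kmax - np.searchsorted(np.cumsum(expected[::-1]), 5.0)
        obs_b = np.concatenate([[observed[: lo + 1].sum()], observed[lo + 1 : hi], [observed[hi:].sum()]])
        exp_b = np.concatenate([[expected[: lo + 1].sum()], expected[lo + 1 : hi], [expected[hi:].sum()]])
        exp_b *= obs_b.sum() / exp_b.sum()
        _, pval = stats.chisquare(obs_b, exp_b)
        assert pval > 0.01

    def test_matches_per_observation_oracle(self, small_panel):
        """Dual route: vectorized sampler vs explicit per-read assignment."""
        tf, e, n_obs, n_trials = 0.3, 0.003, 200, 4000
        fast = simulate_mut_counts(small_panel, n_obs, tf, n_trials, e, seed=8)
        rng = np.random.default_rng(9)
        probs = tf * small_panel.mut_probabilities() + (1 - tf) * e / 3
        slow = np.empty(n_trials, dtype=np.int64)
        for t in range(n_trials):
            sites = rng.integers(0, small_panel.n_sites, size=n_obs)
            slow[t] = np.count_nonzero(rng.random(n_obs) < probs[sites])
        assert abs(fast.mean() - slow.mean()) <= 4 * np.sqrt(fast.var() / n_trials + slow.var() / n_trials)
        assert stats.ks_2samp(fast, slow).pvalue > 0.01


class TestEstimateTF:
    def test_no_mut_no_error_gives_zero(self, small_panel):
        est = estimate_tf_snv(AlleleCounts(1000, 0, 0), small_panel, error_rate=0.0, seed=10)
        assert est.tf_point == 0.0
        assert est.refined
        assert est.grid_weights.sum() == pytest.approx(1.0)
        # All alignment mass sits at TFs whose expected MUT count is tiny.
        expected_counts = 1000 * np.array(
            [marginal_mut_probability(small_panel, tf) for tf in est.grid]
        )
        assert expected_counts[est.grid_weights > 0].max() < 12

    def test_recovers_half(self):
        panel = synth.generate_variant_panel(100, vaf_mean=0.5, vaf_sd=0.0, purity=1.0, seed=11)
        obs = synth.generate_allele_observations(panel, tf=0.5, coverage=100, seed=12)
        est = estimate_tf_snv(count_alleles(obs, panel), panel, seed=13)
        assert 0.45 <= est.tf_point <= 0.55
        assert est.ci_low <= 0.5 <= est.ci_high

    def test_monotone_in_observed_mut_count(self, small_panel):
        points = [
            estimate_tf_snv(AlleleCounts(400 - m, m, 0), small_panel, seed=14).tf_point
            for m in (0, 10, 30, 60, 100)
        ]
        assert points == sorted(points)

    def test_zero_observations_rejected(self, small_panel):
        with pytest.raises(ValueError):
            estimate_tf_snv(AlleleCounts(0, 0, 0), small_panel, seed=15)

    def test_admixture_series_monotone_and_calibrated(self, small_panel):
        """Diluting a high-TF source tracks the expected fraction*TF."""
        # Coverage keeps n_obs ~ 1000 so that the MUT-count distributions of
        # adjacent grid TFs overlap and the interval stays non-degenerate.
        tf_source = 0.71
        obs_t = synth.generate_allele_observations(small_panel, tf_source, 10, 0.00072, seed=16)
        obs_h = synth.generate_allele_observations(small_panel, 0.0, 10, 0.00072, seed=17)
        estimates = []
        for k, frac in enumerate((1.0, 0.10, 0.02)):
            mixed = synth.make_admixture(obs_t, obs_h, frac, seed=18 + k)
            est = estimate_tf_snv(
                count_alleles(mixed, small_panel), small_panel, error_rate=0.00072, seed=21 + k
            )
            estimates.append(est)
            assert est.ci_low <= frac * tf_source <= est.ci_high
        pts = [e.tf_point for e in estimates]
        assert pts == sorted(pts, reverse=True)
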