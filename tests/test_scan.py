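"""G statistic, tri-cube smoothing, log-normal null, peaks, and CIs."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cexqtl.bulkpop import SimConfig
from cexqtl.fixtures import make_fixture_experiment, make_fixture_genome, nearest_marker
from cexqtl.scan import (
    GScan,
    NullFitError,
    call_peaks,
    ci_by_simulation,
    fit_null_lognormal,
    g_statistic,
    nearest_rank_ci,
    p_values,
    tricube_smooth,
    tricube_weights,
)
from cexqtl.selection import EffectSizeModel


class TestGStatistic:
    def test_balanced_counts_give_zero(self):
        assert g_statistic(50, 50, 50, 50, 0.5, 100) == 0.0
        assert g_statistic(50, 50, 50, 50, 0.5, 100, "as-printed-linear") == 0.0

    def test_hand_computed_squared_value(self):
        # N = 0.6(40-60) + 0.4(40-60) = -20; G = 400 / (2*100*0.4*0.6)
        g = g_statistic(60, 40, 40, 60, 0.4, 100)
        assert g == pytest.approx(400.0 / 48.0, rel=1e-9)

    def test_hand_computed_linear_value(self):
        g = g_statistic(60, 40, 40, 60, 0.4, 100, "as-printed-linear")
        assert g == pytest.approx(-20.0 / 48.0, rel=1e-9)

    def test_out_of_range_q_rejected(self):
        with pytest.raises(ValueError):
            g_statistic(1, 1, 1, 1, 0.0, 10)

    def test_squared_variant_invariant_to_pool_swap(self, rng):
        # swapping (n1,n3) <-> (n2,n4) negates the numerator at fixed q
        n = rng.integers(1, 100, size=(50, 4))
        q = rng.uniform(0.1, 0.9, 50)
        g1 = g_statistic(n[:, 0], n[:, 1], n[:, 2], n[:, 3], q, 100)
        g2 = g_statistic(n[:, 1], n[:, 0], n[:, 3], n[:, 2], q, 100)
        np.testing.assert_allclose(g1, g2, rtol=1e-12)


class TestTricube:
    def test_isolated_marker_keeps_raw_g(self):
        out = tricube_smooth(np.array([7.0]), np.array([10.0]), np.array(["c"]))
        assert out[0] == 7.0

    def test_constant_g_unchanged(self):
        cm = np.linspace(0, 20, 30)
        out = tricube_smooth(np.full(30, 3.3), cm, np.array(["c"] * 30))
        np.testing.assert_allclose(out, 3.3, rtol=1e-12)

    def test_two_marker_hand_example(self):
        # distances 0 and 6.25 cM with half-width 12.5: weights 1 and (1-0.5^3)^3
        g = np.array([10.0, 2.0])
        cm = np.array([0.0, 6.25])
        out = tricube_smooth(g, cm, np.array(["c", "c"]), half_width=12.5)
        w = (1 - 0.5 ** 3) ** 3
        expected = (10 + 2 * w) / (1 + w)
        assert out[0] == pytest.approx(expected, rel=1e-9)
        assert w == pytest.approx(0.669921875, rel=1e-12)

    def test_window_excludes_other_chromosomes(self):
        g = np.array([10.0, 0.0])
        cm = np.array([0.0, 0.0])
        out = tricube_smooth(g, cm, np.array(["c1", "c2"]))
        np.testing.assert_allclose(out, g)

    @given(st.lists(st.floats(min_value=0, max_value=50), min_size=2, max_size=20,
                    unique=True))
    def test_weights_normalized_and_peaked_at_focus(self, cms):
        cm = np.sort(np.array(cms))
        d = np.abs(cm - cm[0]) / 12.5
        w = tricube_weights(np.minimum(d, 1.0)) * (d <= 1.0)
        assert w[0] == pytest.approx(1.0)  # focal marker gets the max raw weight
        assert np.all(w <= 1.0) and np.all(w >= 0.0)
        assert np.all(w[d >= 1.0] == 0.0)


class TestLogNormalNull:
    def test_recovers_known_lognormal_parameters(self):
        rng = np.random.default_rng(123)
        x = rng.lognormal(mean=1.0, sigma=0.5, size=10_000)
        mu, sigma = fit_null_lognormal(x)
        assert mu == pytest.approx(1.0, abs=0.03)
        assert sigma == pytest.approx(0.5, abs=0.03)

    def test_robust_to_contamination(self):
        rng = np.random.default_rng(456)
        x = rng.lognormal(1.0, 0.5, 10_000)
        mu_clean, _ = fit_null_lognormal(x)
        x_cont = x.copy()
        idx = rng.choice(x.size, size=x.size // 20, replace=False)
        x_cont[idx] = 100 * np.median(x)
        mu_cont, _ = fit_null_lognormal(x_cont)
        assert abs(mu_cont - mu_clean) < 0.05
        # a mean/SD fit shifts far more under the same contamination
        assert abs(np.log(x_cont).mean() - np.log(x).mean()) > abs(mu_cont - mu_clean)

    def test_degenerate_and_small_samples_rejected(self):
        with pytest.raises(NullFitError, match="degenerate"):
            fit_null_lognormal(np.full(200, 2.0))
        with pytest.raises(NullFitError, match="positive"):
            fit_null_lognormal(np.arange(1.0, 50.0))


class TestPValues:
    def test_median_maps_to_half(self):
        assert p_values(np.array([np.exp(1.3)]), 1.3, 0.7)[0] == pytest.approx(0.5)

    def test_two_sigma_tail(self):
        p = p_values(np.array([np.exp(2.0)]), 0.0, 1.0)[0]
        assert p == pytest.approx(1 - stats.norm.cdf(2), rel=1e-9)
        assert p == pytest.approx(0.02275, abs=1e-5)

    def test_ranking_inverse_to_g(self, rng):
        g = rng.lognormal(0, 1, 500)
        p = p_values(g, 0.0, 1.0)
        assert np.array_equal(np.argsort(g), np.argsort(-p))


class TestPeaks:
    def _table(self, pvals):
        return pd.DataFrame({"chrom": ["c"] * len(pvals),
                             "pos": np.arange(1, len(pvals) + 1), "p": pvals})

    def test_no_signal_no_peaks(self):
        assert call_peaks(self._table([0.5, 0.2, 0.9]), alpha=1e-3) == []

    def test_single_run_single_peak(self):
        peaks = call_peaks(self._table([0.5, 1e-4, 1e-6, 1e-4, 0.5]), alpha=1e-3)
        assert len(peaks) == 1
        assert peaks[0].pos == 3

    def test_two_runs_two_peaks_leftmost_tie(self):
        pv = [1e-4, 1e-4, 0.5, 0.5, 1e-5, 1e-5]
        peaks = call_peaks(self._table(pv), alpha=1e-3)
        assert [p.pos for p in peaks] == [1, 5]  # ties broken leftmost

    def test_nearest_rank_ci_quantile_example(self):
        lo, hi = nearest_rank_ci(np.arange(1, 1001))
        assert (lo, hi) == (26, 975)

    def test_identical_positions_zero_width(self):
        lo, hi = nearest_rank_ci(np.full(100, 42))
        assert (lo, hi) == (42, 42)


class TestRunScan:
    def test_label_swap_leaves_squared_g_unchanged(self, gmap, markers):
        counts, _, _ = make_fixture_experiment(
            "neutral-timecourse", gmap, markers, seed=11,
            config=SimConfig(pop_cap=600, f1_founders=300, generations=4),
            coverage=80, pool_size=150)
        df = counts.df
        q, cov, keep = counts.q_and_coverage()
        g1 = g_statistic(df["n1"][keep], df["n2"][keep], df["n3"][keep],
                         df["n4"][keep], q[keep], cov[keep])
        g2 = g_statistic(df["n2"][keep], df["n1"][keep], df["n4"][keep],
                         df["n3"][keep], q[keep], cov[keep])
        np.testing.assert_allclose(g1, g2, rtol=1e-12)

    def test_planted_locus_is_localized(self):
        # marker spacing must be well below the smoothing window for the
        # G' argmax to localize; use the denser default-scale grid here
        gmap, markers = make_fixture_genome(n_markers=600, seed=7)
        chrom, pos = nearest_marker(markers, "chr4", 0.5)
        cm_true = gmap.bp_to_cm(chrom, pos)
        hits = 0
        for seed in range(5):
            counts, _, _ = make_fixture_experiment(
                "drug-selection", gmap, markers, seed=500 + seed,
                config=SimConfig(pop_cap=10_000, f1_founders=1_000, generations=8),
                effect=EffectSizeModel(chrom, pos, ve=0.2), coverage=100)
            res = GScan(counts, gmap).fit()
            top_chrom, top_pos = res.top_marker()
            if top_chrom == chrom and abs(gmap.bp_to_cm(chrom, top_pos) - cm_true) <= 2.0:
                hits += 1
        assert hits >= 4

    def test_scan_is_deterministic(self, gmap, markers):
        counts, _, _ = make_fixture_experiment(
            "neutral-timecourse", gmap, markers, seed=21,
            config=SimConfig(pop_cap=500, f1_founders=250, generations=3),
            coverage=60, pool_size=100)
        r1 = GScan(counts, gmap).fit()
        r2 = GScan(counts, gmap).fit()
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_summary_mentions_peaks(self, gmap, markers):
        chrom, pos = nearest_marker(markers, "chr2", 0.5)
        counts, _, _ = make_fixture_experiment(
            "drug-selection", gmap, markers, seed=31,
            config=SimConfig(pop_cap=20_000, f1_founders=1_000, generations=8),
            effect=EffectSizeModel(chrom, pos, ve=0.3), coverage=150)
        res = GScan(counts, gmap).fit()
        text = res.summary()
        assert "peaks" in text and "mu" in text


class TestCiBySimulation:
    def test_synthetic_positions_quantiles(self):
        # the CI machinery reduces to nearest-rank quantiles of top positions
        lo, hi = nearest_rank_ci(np.arange(1, 1001))
        assert (lo, hi) == (26, 975)

    def test_ci_contains_peak_and_shrinks_with_ve(self, gmap, markers):
        chrom, pos = nearest_marker(markers, "chr3", 0.4)
        cfg = SimConfig(pop_cap=2_000, f1_founders=1_000, generations=6)
        rng = np.random.default_rng(8)
        lo_w, hi_w, _ = ci_by_simulation(chrom, pos, gmap, markers, cfg, rng,
                                         ve_range=(0.05, 0.05), iterations=40,
                                         coverage=100, min_markers=50)
        rng = np.random.default_rng(8)
        lo_s, hi_s, pos_s = ci_by_simulation(chrom, pos, gmap, markers, cfg, rng,
                                             ve_range=(0.4, 0.4), iterations=40,
                                             coverage=100, min_markers=50)
        assert lo_s <= pos <= hi_s
        assert (hi_s - lo_s) <= (hi_w - lo_w)
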