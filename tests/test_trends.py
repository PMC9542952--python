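import numpy as np
import pandas as pd
import pytest

from carbbudget.trends import (cover_production_fit, cover_production_fits,
                               holocene_comparison, percent_positive,
                               regional_summary)


class TestRegionalSummary:
    def test_two_site_mean_and_se(self):
        budgets = pd.DataFrame({
            "site_id": ["A", "B"], "year": [2000, 2000],
            "gross": [1.0, 3.0], "bioerosion_total": [0.0, 0.0],
            "net": [1.0, 3.0], "rap": [1.0, 3.0]})
        out = regional_summary(budgets)
        assert out["net_mean"].iloc[0] == pytest.approx(2.0)
        assert out["net_se"].iloc[0] == pytest.approx(1.0)

    def test_single_site_se_flagged(self):
        budgets = pd.DataFrame({
            "site_id": ["A"], "year": [2000], "gross": [1.0],
            "bioerosion_total": [0.5], "net": [0.5], "rap": [0.46]})
        out = regional_summary(budgets)
        assert out["net_se"].iloc[0] == 0.0
        assert bool(out["se_undefined"].iloc[0])

    def test_roster_restricts_sites(self):
        budgets = pd.DataFrame({
            "site_id": ["A", "B", "C"], "year": [2000] * 3,
            "gross": [1.0, 3.0, 100.0], "bioerosion_total": [0.0] * 3,
            "net": [1.0, 3.0, 100.0], "rap": [1.0, 3.0, 100.0]})
        out = regional_summary(budgets, roster=["A", "B"])
        assert out["net_mean"].iloc[0] == pytest.approx(2.0)
        assert out["n_sites"].iloc[0] == 2

    def test_matches_generator_ledger_on_noise_free_data(
            self, noise_free_budgets, noise_free_reefscape):
        ledger = noise_free_reefscape.ledger
        merged = noise_free_budgets.merge(ledger, on=["site_id", "year"])
        out = regional_summary(noise_free_budgets)
        truth = merged.groupby("year")["true_net"].mean()
        for _, row in out.iterrows():
            assert row["net_mean"] == pytest.approx(truth[row["year"]],
                                                    abs=1e-12)


class TestPercentPositive:
    def test_26_of_32(self):
        budgets = pd.DataFrame({
            "site_id": [f"S{i}" for i in range(32)], "year": [1996] * 32,
            "net": [1.0] * 26 + [-1.0] * 6, "net_se": [0.1] * 32})
        out = percent_positive(budgets)
        assert out["pct_positive"].iloc[0] == pytest.approx(81.25)
        assert out["n_positive"].iloc[0] == 26

    def test_all_negative_is_zero(self):
        budgets = pd.DataFrame({"site_id": ["A", "B"], "year": [2000] * 2,
                                "net": [-0.1, -0.2], "net_se": [0.0] * 2})
        assert percent_positive(budgets)["pct_positive"].iloc[0] == 0.0

    def test_reference_boundary_inclusive(self):
        budgets = pd.DataFrame({"site_id": ["A", "B"], "year": [2000] * 2,
                                "net": [2.55, 2.54], "net_se": [0.0] * 2})
        out = percent_positive(budgets, reference=2.55)
        assert out["n_above_reference"].iloc[0] == 1

    def test_strictly_positive_boundary(self):
        budgets = pd.DataFrame({"site_id": ["A"], "year": [2000],
                                "net": [0.0], "net_se": [0.0]})
        assert percent_positive(budgets)["n_positive"].iloc[0] == 0

    def test_lower_bound_mode_uses_net_minus_se(self):
        budgets = pd.DataFrame({"site_id": ["A", "B"], "year": [2000] * 2,
                                "net": [0.3, 0.3], "net_se": [0.5, 0.1]})
        out = percent_positive(budgets, lower_bound=True)
        assert out["n_positive"].iloc[0] == 1

    def test_invariant_to_site_order(self, default_budgets):
        shuffled = default_budgets.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(percent_positive(default_budgets),
                                      percent_positive(shuffled))


class TestCoverProductionFit:
    def test_exact_line_threshold_6pct(self):
        c = np.linspace(0, 20, 50)
        pairs = pd.DataFrame({"coral_cover_pct": c, "net": 0.2 * c - 1.2,
                              "year": 2000, "site_id": "S"})
        est = cover_production_fit(pairs)
        assert est.slope == pytest.approx(0.2, abs=1e-9)
        assert est.threshold_cover == pytest.approx(6.0, abs=1e-6)

    def test_parameter_recovery_with_noise(self):
        # generating line G = 0.16 C - 0.96 (threshold 6%), n = 500
        rng = np.random.default_rng(2024)
        c = rng.uniform(0, 25, 500)
        g = 0.16 * c - 0.96 + rng.normal(0, 0.1, 500)
        pairs = pd.DataFrame({"coral_cover_pct": c, "net": g,
                              "year": 2000, "site_id": "S"})
        est = cover_production_fit(pairs)
        assert abs(est.slope - 0.16) < 2 * est.slope_se
        assert est.threshold_cover == pytest.approx(6.0, abs=0.5)

    def test_uniform_downshift_raises_threshold(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(0, 25, 300)
        g = 0.16 * c - 0.96 + rng.normal(0, 0.05, 300)
        pairs = pd.DataFrame({"coral_cover_pct": c, "net": g,
                              "year": 2000, "site_id": "S"})
        shifted = pairs.assign(net=pairs["net"] - 1.15)
        t0 = cover_production_fit(pairs).threshold_cover
        t1 = cover_production_fit(shifted).threshold_cover
        assert t1 > t0

    def test_nonpositive_slope_flagged(self):
        pairs = pd.DataFrame({"coral_cover_pct": [0, 5, 10, 15.0],
                              "net": [1.0, 0.8, 0.6, 0.4],
                              "year": 2000, "site_id": "S"})
        est = cover_production_fit(pairs)
        assert est.threshold_undefined and est.threshold_cover is None

    def test_too_few_pairs_rejected(self):
        pairs = pd.DataFrame({"coral_cover_pct": [1.0, 2.0],
                              "net": [0.1, 0.2], "year": 2000, "site_id": "S"})
        with pytest.raises(ValueError):
            cover_production_fit(pairs)

    def test_period_split_produces_two_fits(self, default_budgets,
                                            default_reefscape):
        from carbbudget.pipeline import coral_cover_table
        cover = coral_cover_table(default_reefscape.benthic)
        pairs = default_budgets.merge(cover, on=["site_id", "year"])
        fits = cover_production_fits(pairs, period_split=2010)
        assert len(fits) == 2
        assert all(f.slope > 0 for f in fits)

    def test_site_demeaning_recovers_within_slope(self):
        # sites differ in intercept; pooled OLS is confounded, demeaned is not
        rng = np.random.default_rng(5)
        rows = []
        for s, (c0, a0) in enumerate([(2, 1.0), (10, -1.0), (20, -3.0)]):
            c = c0 + rng.uniform(-2, 2, 120)
            g = a0 + 0.16 * c + rng.normal(0, 0.02, 120)
            rows.append(pd.DataFrame({"site_id": f"S{s}", "year": 2000,
                                      "coral_cover_pct": c, "net": g}))
        pairs = pd.concat(rows)
        est = cover_production_fit(pairs, demean_by_site=True)
        assert est.slope == pytest.approx(0.16, abs=0.01)


class TestHoloceneComparison:
    def test_1996_exceeds_last_millennium(self):
        summary = pd.DataFrame({"year": [1996], "rap_mean": [1.23],
                                "rap_se": [0.31]})
        out = holocene_comparison(summary, {"last_millennium": 0.17})
        assert bool(out["exceeds_last_millennium"].iloc[0])

    def test_2019_below_mid_holocene(self):
        summary = pd.DataFrame({"year": [2019], "rap_mean": [0.20],
                                "rap_se": [0.12]})
        out = holocene_comparison(summary, {"mid_holocene": 3.0})
        assert not bool(out["exceeds_mid_holocene"].iloc[0])

    def test_empty_baselines_passthrough(self):
        summary = pd.DataFrame({"year": [2000], "rap_mean": [0.5],
                                "rap_se": [0.1]})
        out = holocene_comparison(summary, {})
        assert list(out.columns) == ["year", "rap_mean", "rap_se"]

    def test_slr_lines_carried(self):
        summary = pd.DataFrame({"year": [2000], "rap_mean": [0.5],
                                "rap_se": [0.1]})
        out = holocene_comparison(summary, {}, slr_lines={"recent": 3.6})
        assert not bool(out["keeps_pace_recent"].iloc[0])
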