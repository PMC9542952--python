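import numpy as np
import pandas as pd
import pytest

from carbbudget import bioerosion as be
from carbbudget.reference_data import (ParrotfishRate, ParrotfishRateTable,
                                       UrchinModel)


@pytest.fixture
def unit_rates():
    """One species whose bite parameters are all 1 (12 h foraging)."""
    rows = [ParrotfishRate("Sparisoma viride", phase, 0, 100, 1.0, 1.0, 1.0,
                           1.0, 12.0)
            for phase in ("juvenile", "initial", "terminal")]
    return ParrotfishRateTable(rows)


class TestParrotfishIndividual:
    def test_unit_parameters_give_4_38(self, unit_rates):
        # 1 bite/h x 1 x 1 cm3 x 1 g/cm3 x 12 h x 365 d / 1000 = 4.38 kg/yr
        e = be.parrotfish_individual_erosion("Sparisoma viride", "initial",
                                             20.0, unit_rates)
        assert e == pytest.approx(4.38)

    def test_zero_scar_fraction_gives_zero(self):
        table = ParrotfishRateTable([ParrotfishRate(
            "Sparisoma viride", "initial", 0, 100, 50.0, 0.0, 1.0, 1.7)])
        assert be.parrotfish_individual_erosion(
            "Sparisoma viride", "initial", 20.0, table) == 0.0

    def test_linearity_in_bite_volume(self):
        def table(vol):
            return ParrotfishRateTable([ParrotfishRate(
                "Sparisoma viride", "initial", 0, 100, 50.0, 0.2, vol, 1.7)])
        e1 = be.parrotfish_individual_erosion("Sparisoma viride", "initial",
                                              20.0, table(0.5))
        e2 = be.parrotfish_individual_erosion("Sparisoma viride", "initial",
                                              20.0, table(1.0))
        assert e2 == pytest.approx(2 * e1)

    def test_missing_entry_reports_gap(self, unit_rates):
        with pytest.raises(KeyError, match="Scarus vetula"):
            be.parrotfish_individual_erosion("Scarus vetula", "initial",
                                             20.0, unit_rates)


class TestParrotfishSite:
    def test_one_fish_in_100m2(self, unit_rates):
        census = pd.DataFrame({
            "survey_id": ["V1"], "species": ["Sparisoma viride"],
            "phase": ["initial"], "fork_length_cm": [20.0],
            "count": [1], "area_m2": [100.0]})
        value, se, n, missing = be.parrotfish_site_erosion(census, unit_rates)
        assert value == pytest.approx(0.0438)
        assert n == 1 and not missing

    def test_three_survey_mean_and_se(self, unit_rates):
        # survey erosions {0.1, 0.2, 0.3}: counts scaled against 4.38/m2
        frames = []
        for i, target in enumerate((0.1, 0.2, 0.3), 1):
            frames.append(pd.DataFrame({
                "survey_id": [f"V{i}"], "species": ["Sparisoma viride"],
                "phase": ["initial"], "fork_length_cm": [20.0],
                "count": [1], "area_m2": [4.38 / target]}))
        value, se, n, _ = be.parrotfish_site_erosion(pd.concat(frames),
                                                     unit_rates)
        assert value == pytest.approx(0.2)
        assert se == pytest.approx(0.1 / np.sqrt(3), abs=1e-4)  # 0.0577

    def test_empty_census_flagged(self, unit_rates):
        value, se, n, missing = be.parrotfish_site_erosion(
            pd.DataFrame(columns=["survey_id", "species", "phase",
                                  "fork_length_cm", "count", "area_m2"]),
            unit_rates)
        assert value == 0.0 and missing

    def test_brute_force_per_fish_oracle(self, library):
        """Site erosion equals a naive one-row-per-fish loop, 100 censuses."""
        rng = np.random.default_rng(11)
        species = list(library.parrotfish_rates.species_phases())
        for trial in range(100):
            n_rows = rng.integers(1, 12)
            picks = rng.integers(0, len(species), size=n_rows)
            rows = []
            for j, k in enumerate(picks):
                sp, ph = species[k]
                rows.append({
                    "survey_id": f"V{trial}", "species": sp, "phase": ph,
                    "fork_length_cm": float(rng.uniform(1, 49)),
                    "count": int(rng.integers(0, 20)),
                    "area_m2": 176.7})
            census = pd.DataFrame(rows)
            value, *_ = be.parrotfish_site_erosion(census,
                                                   library.parrotfish_rates)
            # oracle: expand to individual fish, sum each one's erosion
            naive = 0.0
            for r in rows:
                for _ in range(r["count"]):
                    naive += be.parrotfish_individual_erosion(
                        r["species"], r["phase"], r["fork_length_cm"],
                        library.parrotfish_rates)
            naive /= 176.7
            assert value == pytest.approx(naive, rel=1e-9, abs=1e-15)


class TestMatching:
    @pytest.fixture
    def surveys(self):
        return pd.DataFrame({
            "survey_id": [f"V{i}" for i in range(10)],
            "lat": [24.5] * 10, "lon": [-81.0] * 10,
            "habitat": ["patch"] * 10, "depth_m": [6.0] * 10,
            "year": list(range(1998, 2008)),
            "erosion": [0.1] * 10})

    def test_identical_location_same_year_matched(self, surveys):
        out = be.match_fish_surveys(24.5, -81.0, "patch", 2006, surveys)
        assert "V8" in set(out["survey_id"])  # year 2006

    def test_radius_bound_excludes_11km(self, surveys):
        far = surveys.copy()
        far["lat"] = 24.5 + 11.0 / 111.0  # ~11 km north
        out = be.match_fish_surveys(24.5, -81.0, "patch", 2006, far)
        assert out.empty

    def test_radius_inclusive_at_exactly_10km(self):
        surveys = pd.DataFrame({
            "survey_id": ["V1"], "lat": [24.5], "lon": [-81.0],
            "habitat": ["patch"], "depth_m": [6.0], "year": [2006],
            "erosion": [0.1]})
        d = be.great_circle_km(24.5, -81.0, 24.5, -81.0)
        assert d == 0.0
        out = be.match_fish_surveys(24.5, -81.0, "patch", 2006, surveys,
                                    radius_km=0.0)
        assert len(out) == 1

    def test_trailing_window_bound(self, surveys):
        out = be.match_fish_surveys(24.5, -81.0, "patch", 2006, surveys,
                                    window_years=8)
        years = set(out["year"])
        assert years == set(range(1999, 2007))  # 1998 excluded, 2007 future

    def test_habitat_mismatch_excluded(self, surveys):
        out = be.match_fish_surveys(24.5, -81.0, "offshore deep", 2006,
                                    surveys)
        assert out.empty

    def test_depth_outside_band_excluded(self, surveys):
        deep = surveys.assign(habitat="offshore shallow", depth_m=9.0)
        out = be.match_fish_surveys(24.5, -81.0, "offshore shallow", 2006,
                                    deep)
        assert out.empty  # 9 m is outside the 1.8-7.3 m shallow band


class TestUrchin:
    def test_zero_density(self, library):
        assert be.urchin_erosion(0.0, library.urchin_model) == 0.0

    def test_point_mass_at_1cm(self):
        model = UrchinModel(a=1000.0, b=2.7, sizes_cm=(1.0,), pmf=(1.0,))
        assert be.urchin_erosion(1.0, model) == pytest.approx(1.0)

    def test_hand_summed_expectation(self):
        # density 2 x (0.5*10*4^1? ) -> 2 x (0.5*40 + 0.5*160)/1000 = 0.2
        model = UrchinModel(a=10.0, b=2.0, sizes_cm=(2.0, 4.0), pmf=(0.5, 0.5))
        assert be.urchin_erosion(2.0, model) == pytest.approx(0.2)


class TestSpongeAndMicro:
    def test_sponge_zero_area(self, library):
        assert be.sponge_erosion({}, library.sponge_rates) == 0.0

    def test_sponge_linearity(self, library):
        a = be.sponge_erosion({"Cliona varians": 0.001}, library.sponge_rates)
        b = be.sponge_erosion({"Cliona varians": 0.002}, library.sponge_rates)
        assert b == pytest.approx(2 * a)

    def test_sponge_two_species_hand_sum(self):
        rates = {"Cliona varians": 2.0, "Pione lampa": 4.0}
        out = be.sponge_erosion({"Cliona varians": 0.5, "Pione lampa": 0.25},
                                rates)
        assert out == pytest.approx(0.5 * 2.0 + 0.25 * 4.0)

    def test_unknown_sponge_is_error(self, library):
        with pytest.raises(KeyError):
            be.sponge_erosion({"Aplysina fistularis": 0.1},
                              library.sponge_rates)

    def test_omitted_bioeroder_ignored_with_warning(self, library, caplog):
        with caplog.at_level("WARNING"):
            out = be.sponge_erosion({"Siphonodictyon spp.": 0.5},
                                    library.sponge_rates)
        assert out == 0.0
        assert any("Siphonodictyon" in r.message for r in caplog.records)

    @pytest.mark.parametrize("fraction,rate,expected", [
        (0.0, 0.3, 0.0), (1.0, 0.3, 0.3), (0.5, 0.3, 0.15)])
    def test_micro(self, fraction, rate, expected):
        assert be.micro_erosion(fraction, rate) == pytest.approx(expected)


class TestComponentTable:
    def test_total_is_component_sum(self, default_budgets):
        total = default_budgets[["parrotfish", "urchin", "sponge",
                                 "micro"]].sum(axis=1)
        assert np.allclose(total, default_budgets["bioerosion_total"],
                           atol=1e-12)

    def test_components_nonnegative(self, default_budgets):
        for c in ("parrotfish", "urchin", "sponge", "micro"):
            assert (default_budgets[c] >= 0).all()

    def test_omitted_urchins_never_contribute(self, library,
                                              default_reefscape):
        d = default_reefscape
        fish = d.fish.copy()
        poisoned = fish.head(5).assign(species="Echinometra lucunter",
                                       count=10_000)
        fish = pd.concat([fish, poisoned], ignore_index=True)
        years = [2010]
        a = be.bioerosion_table(d.sites.head(3), years, d.fish, d.urchins,
                                d.sponges, d.substrate, library)
        b = be.bioerosion_table(d.sites.head(3), years, fish, d.urchins,
                                d.sponges, d.substrate, library)
        pd.testing.assert_frame_equal(a, b)

    def test_sponge_and_micro_static_across_years(self, default_budgets):
        for c in ("sponge", "micro"):
            per_site = default_budgets.groupby("site_id")[c].nunique()
            assert (per_site == 1).all()
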