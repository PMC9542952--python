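"""Synthetic reefscape generator.

Emulates the statistical structure of the Florida Keys monitoring data the
budget pipeline consumes: annual benthic point-count transects at 46 sites
(a 32-site core surveyed from 1996, plus later additions) across four
subregions and three habitats; stationary fish censuses with species x
life-phase x fork-length counts near each site; and static urchin-density,
sponge-cover, and consolidated-substrate tables.

Site cover follows a multiplicative random walk around habitat-specific
initial means, with pulse disturbances (1997-98 bleaching, a 2005
bleaching/hurricane season, the 2010 cold-water event, 2014/15 bleaching,
and stony coral tissue loss disease arriving in the Upper Keys in 2017 and
reaching the Lower Keys by 2019) applied as taxon- and stratum-specific
survival multipliers.  There are no recovery dynamics by default.

Alongside the observable tables the generator emits a true-state ledger:
latent per-site-year covers, the gross production they imply, and the
exact per-component bioerosion implied by the emitted census tables,
computed here with independent plain loops so the pipeline can be checked
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reference_data import RateLibrary, load_rate_tables

SUBREGIONS = ("Upper Keys", "Middle Keys", "Lower Keys", "Dry Tortugas")
HABITATS = ("patch", "offshore shallow", "offshore deep")

#: representative site depth (m) per habitat, inside each habitat's band
_HABITAT_DEPTH = {"patch": 6.0, "offshore shallow": 4.5, "offshore deep": 13.0}

BARE_SUBSTRATE = "bare substrate"


@dataclass(frozen=True)
class Event:
    """A pulse disturbance: survival multipliers by taxon, in one stratum.

    ``subregions``/``habitats`` of None mean "all".  Multipliers apply to
    latent cover from ``year`` onward.
    """

    year: int
    multipliers: dict[str, float]
    subregions: tuple[str, ...] | None = None
    habitats: tuple[str, ...] | None = None

    def applies(self, subregion: str, habitat: str) -> bool:
        return ((self.subregions is None or subregion in self.subregions)
                and (self.habitats is None or habitat in self.habitats))


def default_events() -> list[Event]:
    keys = ("Upper Keys", "Middle Keys", "Lower Keys")
    return [
        # 1997-98 global bleaching: near-extirpation of A. palmata offshore
        Event(1998, {"Acropora palmata": 0.08, "Acropora cervicornis": 0.3,
                     "Orbicella spp.": 0.85, "Porites astreoides": 0.9,
                     "Montastraea cavernosa": 0.9, "Colpophyllia natans": 0.9},
              subregions=None, habitats=("offshore shallow", "offshore deep")),
        Event(1998, {"Orbicella spp.": 0.92, "Porites astreoides": 0.95,
                     "Montastraea cavernosa": 0.95},
              subregions=None, habitats=("patch",)),
        # 2005 bleaching + hurricane season: mild, regionwide
        Event(2005, {"Orbicella spp.": 0.95, "Acropora palmata": 0.9,
                     "Porites astreoides": 0.95, "Montastraea cavernosa": 0.95,
                     "Colpophyllia natans": 0.95}),
        # January 2010 cold-water event: inshore patch reefs of the Upper
        # and Middle Keys, Orbicella hit hardest
        Event(2010, {"Orbicella spp.": 0.25, "Porites astreoides": 0.75,
                     "Montastraea cavernosa": 0.8, "Colpophyllia natans": 0.8,
                     "Siderastrea siderea": 0.9},
              subregions=("Upper Keys", "Middle Keys"), habitats=("patch",)),
        # 2014/15 bleaching: offshore, mild
        Event(2014, {"Orbicella spp.": 0.93, "Acropora palmata": 0.9},
              habitats=("offshore shallow", "offshore deep")),
        Event(2015, {"Orbicella spp.": 0.95},
              habitats=("offshore shallow", "offshore deep")),
        # SCTLD, staggered Upper 2017 -> Middle 2018 -> Lower 2019
        *[Event(yr, {"Orbicella spp.": 0.55, "Siderastrea siderea": 0.85,
                     "Montastraea cavernosa": 0.7, "Colpophyllia natans": 0.6},
                subregions=(sub,))
          for yr, sub in ((2017, "Upper Keys"), (2018, "Middle Keys"),
                          (2019, "Lower Keys"))],
    ]


def default_initial_cover() -> dict[str, dict[str, float]]:
    """Mean initial percent cover per habitat x taxon (1996)."""
    return {
        "patch": {"Orbicella spp.": 8.0, "Siderastrea siderea": 2.5,
                  "Porites astreoides": 2.0, "Montastraea cavernosa": 1.5,
                  "Colpophyllia natans": 1.0, "CCA": 4.0},
        "offshore shallow": {"Acropora palmata": 3.3, "Orbicella spp.": 2.5,
                             "Siderastrea siderea": 1.0, "Porites astreoides": 1.5,
                             "Montastraea cavernosa": 0.8,
                             "Colpophyllia natans": 0.5,
                             "Acropora cervicornis": 0.3, "CCA": 5.0},
        "offshore deep": {"Orbicella spp.": 2.2, "Montastraea cavernosa": 1.2,
                          "Siderastrea siderea": 1.0, "Porites astreoides": 1.0,
                          "Colpophyllia natans": 0.6, "CCA": 5.0},
    }


def default_fish_densities() -> dict[str, float]:
    """Mean individuals per 176.7 m2 stationary survey, by species."""
    return {
        "Sparisoma viride": 14.0, "Scarus vetula": 5.0,
        "Sparisoma rubripinne": 3.0, "Sparisoma chrysopterum": 3.0,
        "Sparisoma aurofrenatum": 6.0, "Scarus taeniopterus": 9.0,
        "Scarus iseri": 15.0, "Scarus guacamaia": 0.5,
        "Scarus coelestinus": 0.3,
    }


#: life-phase mix and the fork-length class (midpoint, cm) each phase occupies
_PHASE_MIX = {"juvenile": (0.2, 8.0), "initial": (0.5, 25.0),
              "terminal": (0.3, 35.0)}

SURVEY_AREA_M2 = 176.7  # 7.5-m-radius stationary cylinder


@dataclass
class ReefscapeConfig:
    """Knobs of the synthetic reefscape; defaults are the study conditions."""

    years: tuple[int, int] = (1996, 2019)
    seed: int = 0
    points_per_transect: int | None = 1000  # None = exact (noise-free) cover
    cover_noise_sd: float = 0.08   # lognormal sd of the annual multiplicative step
    site_spread_sd: float = 0.4    # lognormal sd of site deviation from habitat mean
    growth: dict[str, float] = field(
        default_factory=lambda: {"Siderastrea siderea": 1.02})
    initial_cover: dict[str, dict[str, float]] = field(
        default_factory=default_initial_cover)
    events: list[Event] = field(default_factory=default_events)
    fish_densities: dict[str, float] = field(default_factory=default_fish_densities)
    fish_count_noise: bool = True  # Poisson counts; False = deterministic rounding
    rvc_surveys_per_site_year: int = 2
    fish_years: tuple[int, int] = (1996, 2019)
    urchin_density_mean: float = 0.0015  # individuals m-2
    sponge_area_mean: float = 0.001      # m2 sponge per m2 reef, total
    substrate_fraction_mean: float = 0.70
    transects_choices: tuple[int, ...] = (2, 3, 4)

    def noise_free(self) -> "ReefscapeConfig":
        """Copy with all stochastic observation/process noise disabled."""
        return replace(self, points_per_transect=None, cover_noise_sd=0.0,
                       site_spread_sd=0.0, fish_count_noise=False,
                       rvc_surveys_per_site_year=1)


@dataclass
class ReefscapeData:
    sites: pd.DataFrame      # site_id, subregion, habitat, lat, lon, depth_m, first_year
    benthic: pd.DataFrame    # site_id, year, transect_id, taxon, cover_pct
    fish: pd.DataFrame       # survey records
    urchins: pd.DataFrame
    sponges: pd.DataFrame
    substrate: pd.DataFrame
    ledger: pd.DataFrame     # true per-site-year state and component erosion
    latent_cover: pd.DataFrame  # site_id, year, taxon, cover_pct (truth)


def _site_roster() -> pd.DataFrame:
    """The 46-site roster: 32-site 1996 core + 2004/2009 additions."""
    rows = []
    counts = {  # (subregion) -> habitat counts for the 1996 core
        "Upper Keys": {"patch": 4, "offshore shallow": 4, "offshore deep": 3},
        "Middle Keys": {"patch": 4, "offshore shallow": 4, "offshore deep": 3},
        "Lower Keys": {"patch": 4, "offshore shallow": 4, "offshore deep": 2},
    }
    lon0 = {"Upper Keys": -80.3, "Middle Keys": -80.9, "Lower Keys": -81.5,
            "Dry Tortugas": -82.9}
    i = 0
    for sub, habs in counts.items():
        for hab, n in habs.items():
            for k in range(n):
                rows.append((f"S{i:02d}", sub, hab, 1996))
                i += 1
    for sub in ("Upper Keys", "Middle Keys", "Lower Keys"):  # 2009 patch additions
        for k in range(2):
            rows.append((f"S{i:02d}", sub, "patch", 2009))
            i += 1
    for hab, n in (("patch", 2), ("offshore shallow", 3), ("offshore deep", 3)):
        for k in range(n):  # Dry Tortugas, added 2004
            rows.append((f"S{i:02d}", "Dry Tortugas", hab, 2004))
            i += 1
    df = pd.DataFrame(rows, columns=["site_id", "subregion", "habitat",
                                     "first_year"])
    # metrically consistent synthetic coordinates: ~6 km spacing along-shore
    df["lon"] = [lon0[s] + 0.06 * (j % 12) for j, s in enumerate(df["subregion"])]
    df["lat"] = [24.55 + 0.1 * (HABITATS.index(h)) + 0.005 * (j % 5)
                 for j, h in enumerate(df["habitat"])]
    df["depth_m"] = df["habitat"].map(_HABITAT_DEPTH)
    return df


def point_count_cover(latent: dict[str, float], n_points: int,
                      rng: np.random.Generator) -> dict[str, float]:
    """Observe a cover vector by classifying ``n_points`` random points.

    ``latent`` must sum to 100 (include the substrate category).  Returns
    percent cover 100 * points / n; an unbiased estimate of the latent cover.
    """
    if n_points < 1:
        raise ValueError("point count requires n_points >= 1")
    taxa = list(latent)
    p = np.asarray([latent[t] for t in taxa], dtype=float)
    if abs(p.sum() - 100.0) > 1e-6:
        raise ValueError("latent covers must sum to 100")
    counts = rng.multinomial(n_points, p / p.sum())
    return {t: 100.0 * c / n_points for t, c in zip(taxa, counts)}


def _validate_events(events: list[Event], taxa: set[str]) -> None:
    for ev in events:
        for t in ev.multipliers:
            if t not in taxa:
                raise ValueError(f"event in {ev.year} references unknown taxon {t!r}")
            if not 0 <= ev.multipliers[t] <= 1:
                raise ValueError(f"event survival multiplier out of [0,1] for {t!r}")
        for s in ev.subregions or ():
            if s not in SUBREGIONS:
                raise ValueError(f"event references unknown subregion {s!r}")
        for h in ev.habitats or ():
            if h not in HABITATS:
                raise ValueError(f"event references unknown habitat {h!r}")


def simulate_reefscape(config: ReefscapeConfig | None = None,
                       library: RateLibrary | None = None) -> ReefscapeData:
    """Generate one synthetic reefscape; deterministic given ``config.seed``."""
    cfg = config or ReefscapeConfig()
    lib = library or load_rate_tables()
    rng = np.random.default_rng(cfg.seed)
    sites = _site_roster()
    all_taxa = {t for cov in cfg.initial_cover.values() for t in cov}
    _validate_events(cfg.events, all_taxa)
    y0, y1 = cfg.years
    years = list(range(y0, y1 + 1))

    # ---- latent cover trajectories -------------------------------------
    latent_rows = []
    site_latent: dict[str, dict[int, dict[str, float]]] = {}
    for site in sites.itertuples():
        base = cfg.initial_cover[site.habitat]
        spread = {t: float(np.exp(rng.normal(0.0, cfg.site_spread_sd)))
                  for t in base}
        cover = {t: base[t] * spread[t] for t in base}
        traj: dict[int, dict[str, float]] = {}
        for year in years:
            if year > y0:
                for t in cover:
                    step = cfg.growth.get(t, 1.0)
                    if cfg.cover_noise_sd > 0:
                        step *= float(np.exp(rng.normal(0.0, cfg.cover_noise_sd)))
                    cover[t] *= step
            for ev in cfg.events:
                if ev.year == year and ev.applies(site.subregion, site.habitat):
                    for t, m in ev.multipliers.items():
                        if t in cover:
                            cover[t] *= m
            total = sum(cover.values())
            if total > 95.0:  # keep room for substrate; rescale pathological sites
                cover = {t: c * 95.0 / total for t, c in cover.items()}
            traj[year] = dict(cover)
            # truth is recorded for every year, even before monitoring began
            for t, c in cover.items():
                latent_rows.append((site.site_id, year, t, c))
        site_latent[site.site_id] = traj
    latent_df = pd.DataFrame(latent_rows,
                             columns=["site_id", "year", "taxon", "cover_pct"])

    # ---- benthic point-count observations ------------------------------
    benthic_rows = []
    for site in sites.itertuples():
        n_transects = (2 if len(cfg.transects_choices) == 1 else
                       int(rng.choice(cfg.transects_choices)))
        if len(cfg.transects_choices) == 1:
            n_transects = cfg.transects_choices[0]
        for year in years:
            if year < site.first_year:
                continue
            truth = site_latent[site.site_id][year]
            vec = dict(truth)
            vec[BARE_SUBSTRATE] = 100.0 - sum(truth.values())
            for tr in range(1, n_transects + 1):
                if cfg.points_per_transect is None:
                    obs = vec
                else:
                    obs = point_count_cover(vec, cfg.points_per_transect, rng)
                for t, c in obs.items():
                    benthic_rows.append((site.site_id, year, f"T{tr}", t, c))
    benthic = pd.DataFrame(benthic_rows, columns=["site_id", "year",
                                                  "transect_id", "taxon",
                                                  "cover_pct"])

    # ---- fish censuses --------------------------------------------------
    fy0, fy1 = cfg.fish_years
    fish_rows = []
    survey_no = 0
    for site in sites.itertuples():
        for year in range(fy0, fy1 + 1):
            for s in range(cfg.rvc_surveys_per_site_year):
                survey_no += 1
                sid = f"RVC{survey_no:05d}"
                if cfg.fish_count_noise:
                    lat = site.lat + float(rng.normal(0, 0.01))
                    lon = site.lon + float(rng.normal(0, 0.01))
                else:
                    lat, lon = site.lat, site.lon
                for species, dens in cfg.fish_densities.items():
                    for phase, (frac, length) in _PHASE_MIX.items():
                        mean_count = dens * frac
                        if cfg.fish_count_noise:
                            count = int(rng.poisson(mean_count))
                        else:
                            count = int(round(mean_count))
                        if count == 0:
                            continue
                        fish_rows.append((sid, lat, lon, site.habitat,
                                          site.depth_m, year, species, phase,
                                          length, count, SURVEY_AREA_M2))
    fish = pd.DataFrame(fish_rows, columns=["survey_id", "lat", "lon",
                                            "habitat", "depth_m", "year",
                                            "species", "phase",
                                            "fork_length_cm", "count",
                                            "area_m2"])

    # ---- static urchin / sponge / substrate tables ----------------------
    def _static(mean: float) -> np.ndarray:
        if cfg.cover_noise_sd == 0 and cfg.site_spread_sd == 0:
            return np.full(len(sites), mean)
        return mean * np.exp(rng.normal(0.0, 0.3, size=len(sites)))

    urchins = pd.DataFrame({"site_id": sites["site_id"],
                            "density_m2": _static(cfg.urchin_density_mean)})
    sponge_species = list(lib.sponge_rates)
    sp_rows = []
    areas = _static(cfg.sponge_area_mean)
    for sid, total_area in zip(sites["site_id"], areas):
        for j, sp in enumerate(sponge_species):
            sp_rows.append((sid, sp, total_area / len(sponge_species)))
    sponges = pd.DataFrame(sp_rows, columns=["site_id", "species",
                                             "area_m2_per_m2"])
    substrate = pd.DataFrame({
        "site_id": sites["site_id"],
        "consolidated_fraction": np.clip(_static(cfg.substrate_fraction_mean),
                                         0.0, 1.0)})

    ledger = _true_state_ledger(sites, latent_df, fish, urchins, sponges,
                                substrate, lib)
    return ReefscapeData(sites=sites, benthic=benthic, fish=fish,
                         urchins=urchins, sponges=sponges,
                         substrate=substrate, ledger=ledger,
                         latent_cover=latent_df)


def _true_state_ledger(sites, latent, fish, urchins, sponges, substrate,
                       lib: RateLibrary) -> pd.DataFrame:
    """Truth implied by the emitted tables, via independent plain loops."""
    rate = {t: lib.taxon_rates[t].g_rate for t in lib.taxon_rates.taxa()}

    # per-fish erosion, naive loop over the emitted records
    survey_erosion: dict[str, float] = {}
    survey_meta: dict[str, tuple[float, float, str, int]] = {}
    for row in fish.itertuples():
        r = lib.parrotfish_rates.lookup(row.species, row.phase,
                                        row.fork_length_cm)
        e = (r.bite_rate * r.prop_scars * r.bite_volume * r.substrate_density
             * r.foraging_hours * 365.0 / 1000.0)
        survey_erosion[row.survey_id] = (survey_erosion.get(row.survey_id, 0.0)
                                         + row.count * e / row.area_m2)
        survey_meta[row.survey_id] = (row.lat, row.lon, row.habitat, row.year)

    u_g = 0.0  # expected grams per urchin
    for s, p in zip(lib.urchin_model.sizes_cm, lib.urchin_model.pmf):
        u_g += p * lib.urchin_model.a * s ** lib.urchin_model.b
    urchin_by_site = dict(zip(urchins["site_id"], urchins["density_m2"]))
    substrate_by_site = dict(zip(substrate["site_id"],
                                 substrate["consolidated_fraction"]))
    sponge_by_site: dict[str, float] = {}
    for row in sponges.itertuples():
        sponge_by_site[row.site_id] = (sponge_by_site.get(row.site_id, 0.0)
                                       + row.area_m2_per_m2
                                       * lib.sponge_rates[row.species])

    site_info = {s.site_id: s for s in sites.itertuples()}
    rows = []
    for (sid, year), g in latent.groupby(["site_id", "year"]):
        gross = 0.0
        for t, c in zip(g["taxon"], g["cover_pct"]):
            gross += c / 100.0 * rate.get(t, 0.0)
        # parrotfish truth: mean over this site's own surveys in the
        # trailing 8-year window (matching the pipeline's averaging rule)
        info = site_info[sid]
        vals = [v for svid, v in survey_erosion.items()
                if (survey_meta[svid][2] == info.habitat
                    and abs(survey_meta[svid][0] - info.lat) < 0.02
                    and abs(survey_meta[svid][1] - info.lon) < 0.02
                    and year - 8 < survey_meta[svid][3] <= year)]
        pf = sum(vals) / len(vals) if vals else float("nan")
        rows.append({
            "site_id": sid, "year": int(year),
            "true_coral_cover": float(g.loc[g["taxon"] != "CCA",
                                            "cover_pct"].sum()),
            "true_gross": gross,
            "true_parrotfish": pf,
            "true_urchin": urchin_by_site[sid] * u_g / 1000.0,
            "true_sponge": sponge_by_site.get(sid, 0.0),
            "true_micro": substrate_by_site[sid] * lib.micro_rate,
        })
    df = pd.DataFrame(rows)
    df["true_erosion"] = df[["true_parrotfish", "true_urchin", "true_sponge",
                             "true_micro"]].sum(axis=1)
    df["true_net"] = df["true_gross"] - df["true_erosion"]
    return df.sort_values(["site_id", "year"]).reset_index(drop=True)
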