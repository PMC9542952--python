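"""The four bioerosion components: parrotfish, urchin, sponge, micro.

Parrotfish erosion comes from stationary fish-census size-frequency data
matched to each benthic site (same habitat class, depth inside the habitat
band, great-circle distance <= 10 km, survey year inside a trailing 8-year
window).  Urchin erosion uses a power law over an empirical test-size
distribution because surveys record density but not sizes.  Sponge and
microbioerosion are static site means replicated across years, since the
underlying census variables were not collected every year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .reference_data import (OMITTED_BIOERODERS, ParrotfishRate,
                             ParrotfishRateTable, RateLibrary, UrchinModel)

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: depth band (m) defining "similar depth" per habitat class
HABITAT_DEPTH_BANDS: dict[str, tuple[float, float]] = {
    "patch": (1.8, 12.8),
    "offshore shallow": (1.8, 7.3),
    "offshore deep": (10.7, 16.5),
}


@dataclass
class BioerosionComponents:
    """Per-site-year bioerosion, each kg CaCO3 m-2 yr-1."""

    site_id: str
    year: int
    parrotfish: float
    urchin: float
    sponge: float
    micro: float
    parrotfish_se: float = 0.0
    n_fish_surveys: int = 0
    no_fish_data: bool = False

    @property
    def total(self) -> float:
        return self.parrotfish + self.urchin + self.sponge + self.micro


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Spherical-earth (haversine) distance in km; accepts arrays."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def parrotfish_individual_erosion(species: str, phase: str, fork_length: float,
                                  rates: ParrotfishRateTable) -> float:
    """Annual erosion of one fish, kg CaCO3 yr-1.

    bite_rate x prop_scars x bite_volume x substrate_density gives g h-1;
    annualized over foraging_hours per day x 365 days and converted to kg.
    """
    r = rates.lookup(species, phase, fork_length)
    return _individual_erosion(r)


def _individual_erosion(r: ParrotfishRate) -> float:
    return (r.bite_rate * r.prop_scars * r.bite_volume * r.substrate_density
            * r.foraging_hours * 365.0 / 1000.0)


def parrotfish_survey_erosion(census: pd.DataFrame,
                              rates: ParrotfishRateTable) -> float:
    """Areal erosion of a single survey: sum(count x individual) / area."""
    if census.empty:
        return 0.0
    area = float(census["area_m2"].iloc[0])
    if area <= 0:
        raise ValueError("survey area must be positive")
    total = 0.0
    for row in census.itertuples():
        total += row.count * parrotfish_individual_erosion(
            str(row.species), str(row.phase), float(row.fork_length_cm), rates)
    return total / area


def parrotfish_site_erosion(matched: pd.DataFrame,
                            rates: ParrotfishRateTable
                            ) -> tuple[float, float, int, bool]:
    """Mean (+SE) parrotfish erosion over matched surveys.

    Returns ``(value, se, n_surveys, no_fish_data)``; an empty census gives
    zero with the ``no_fish_data`` flag set.
    """
    if matched.empty:
        return 0.0, 0.0, 0, True
    per_survey = []
    for _, census in matched.groupby("survey_id", observed=True):
        per_survey.append(parrotfish_survey_erosion(census, rates))
    arr = np.asarray(per_survey, dtype=float)
    n = arr.size
    se = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(arr.mean()), se, n, False


def match_fish_surveys(site_lat: float, site_lon: float, habitat: str,
                       year: int, fish: pd.DataFrame,
                       radius_km: float = 10.0,
                       window_years: int = 8) -> pd.DataFrame:
    """Select fish-census records usable for one benthic site-year.

    Keeps surveys with great-circle distance <= ``radius_km`` (inclusive),
    identical habitat class, depth inside the habitat's depth band, and
    survey year in the trailing window ``[year - window_years + 1, year]``.
    """
    if fish.empty:
        return fish
    year_col = fish["year"] if "year" in fish.columns else \
        pd.to_datetime(fish["date"]).dt.year
    dist = great_circle_km(site_lat, site_lon,
                           fish["lat"].to_numpy(), fish["lon"].to_numpy())
    lo, hi = HABITAT_DEPTH_BANDS.get(habitat, (-np.inf, np.inf))
    mask = ((dist <= radius_km)
            & (fish["habitat"] == habitat)
            & (fish["depth_m"] >= lo) & (fish["depth_m"] <= hi)
            & (year_col > year - window_years) & (year_col <= year))
    return fish[mask]


def urchin_erosion(density: float, model: UrchinModel) -> float:
    """Urchin erosion, kg CaCO3 m-2 yr-1, from density (individuals m-2)."""
    if density < 0:
        raise ValueError("urchin density must be >= 0")
    return density * model.per_individual_g() / 1000.0


def sponge_erosion(area_by_species: Mapping[str, float],
                   sponge_rates: Mapping[str, float]) -> float:
    """Sponge macro-bioerosion from occupied surface area (m2 per m2 reef).

    Linear in area x species rate.  Species excluded from the survey design
    are ignored with a warning; any other unknown species is an error.
    """
    total = 0.0
    for species, area in area_by_species.items():
        if area < 0:
            raise ValueError(f"negative sponge area for {species!r}")
        if species in OMITTED_BIOERODERS:
            logger.warning("ignoring omitted bioeroder %r", species)
            continue
        if species not in sponge_rates:
            raise KeyError(f"unknown bioeroding sponge species {species!r}")
        total += area * sponge_rates[species]
    return total


def micro_erosion(substrate_fraction: float, micro_rate: float) -> float:
    """Microbioerosion from the available consolidated-substrate fraction."""
    if not 0 <= substrate_fraction <= 1:
        raise ValueError("substrate fraction must be in [0, 1]")
    return substrate_fraction * micro_rate


def bioerosion_table(sites: pd.DataFrame, years: list[int] | np.ndarray,
                     fish: pd.DataFrame, urchins: pd.DataFrame,
                     sponges: pd.DataFrame, substrate: pd.DataFrame,
                     library: RateLibrary,
                     radius_km: float = 10.0, window_years: int = 8,
                     missing_fish: str = "habitat_mean") -> pd.DataFrame:
    """All four components for every site-year.

    Parameters
    ----------
    sites
        One row per site: site_id, lat, lon, habitat.
    fish
        survey_id, lat, lon, habitat, depth_m, year (or date), species,
        phase, fork_length_cm, count, area_m2.  Urchin or sponge taxa
        outside the survey design are dropped with a warning.
    urchins
        site_id, density_m2 (static per site).
    sponges
        site_id, species, area_m2_per_m2 (static per site).
    substrate
        site_id, consolidated_fraction (static per site).
    missing_fish
        "habitat_mean" substitutes the mean parrotfish erosion over all
        surveys of the site's habitat when nothing matches (flagged);
        "zero" leaves it at 0.
    """
    fish = fish[~fish["species"].isin(OMITTED_BIOERODERS)] if not fish.empty else fish

    # precompute per-survey areal erosion once; matching then just filters rows
    if fish.empty:
        surveys = pd.DataFrame(columns=["survey_id", "lat", "lon", "habitat",
                                        "depth_m", "year", "erosion"])
    else:
        per = []
        for sid_, census in fish.groupby("survey_id", observed=True):
            first = census.iloc[0]
            per.append((sid_, first["lat"], first["lon"], first["habitat"],
                        first["depth_m"], int(first["year"]),
                        parrotfish_survey_erosion(census, library.parrotfish_rates)))
        surveys = pd.DataFrame(per, columns=["survey_id", "lat", "lon",
                                             "habitat", "depth_m", "year",
                                             "erosion"])

    urchin_by_site = dict(zip(urchins["site_id"], urchins["density_m2"]))
    sponge_by_site = {
        sid: sponge_erosion(dict(zip(g["species"], g["area_m2_per_m2"])),
                            library.sponge_rates)
        for sid, g in sponges.groupby("site_id", observed=True)}
    substrate_by_site = dict(zip(substrate["site_id"],
                                 substrate["consolidated_fraction"]))

    # per-habitat fallback: mean erosion over every survey of that habitat
    habitat_means: dict[str, float] = {}
    if not surveys.empty and missing_fish == "habitat_mean":
        habitat_means = surveys.groupby("habitat")["erosion"].mean().to_dict()

    rows = []
    for site in sites.itertuples():
        u = urchin_erosion(float(urchin_by_site.get(site.site_id, 0.0)),
                           library.urchin_model)
        s = float(sponge_by_site.get(site.site_id, 0.0))
        m = micro_erosion(float(substrate_by_site.get(site.site_id, 0.0)),
                          library.micro_rate)
        for year in years:
            matched = match_fish_surveys(site.lat, site.lon, site.habitat,
                                         int(year), surveys, radius_km,
                                         window_years)
            vals = matched["erosion"].to_numpy(dtype=float)
            missing = vals.size == 0
            n = int(vals.size)
            pf = float(vals.mean()) if n else 0.0
            pf_se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            if missing and missing_fish == "habitat_mean":
                pf = habitat_means.get(site.habitat, 0.0)
            rows.append({
                "site_id": site.site_id, "year": int(year),
                "parrotfish": pf, "parrotfish_se": pf_se,
                "urchin": u, "sponge": s, "micro": m,
                "n_fish_surveys": n, "no_fish_data": missing,
            })
    out = pd.DataFrame(rows)
    out["bioerosion_total"] = out[["parrotfish", "urchin", "sponge", "micro"]].sum(axis=1)
    return out
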