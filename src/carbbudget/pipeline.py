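"""End-to-end orchestration: surveys in, budgets / trends / scenarios out.

``run_pipeline`` chains the stages deterministically and drops a JSON
provenance sidecar (parameters, seed, input checksums, package version)
next to the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bioerosion import bioerosion_table
from .budget import apply_erosion_offset, assemble_budgets
from .io import write_table
from .production import gross_production_table
from .reference_data import RateLibrary, load_rate_tables
from .scenarios import apply_scenario, scenario_sweep
from .synthetic import BARE_SUBSTRATE
from .trends import (cover_production_fits, holocene_comparison,
                     percent_positive, regional_summary)

logger = logging.getLogger(__name__)

NON_CORAL = (BARE_SUBSTRATE, "CCA")


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    out_dir: Path
    rates_path: Path | None = None     # override directory for rate tables
    offset_kg: float = 0.0             # geologic erosion allowance to apply
    radius_km: float = 10.0            # fish-survey matching radius
    window_years: int = 8              # trailing running-mean window
    reference: float = 2.55            # western Atlantic mean, kg m-2 yr-1
    roster: list[str] | None = None    # fixed site subset for trend series
    scenario_year: int | None = None   # baseline year for restoration scenarios
    sweep: dict[str, list[float]] = field(default_factory=dict)
    seed: int | None = None            # recorded in provenance only


def coral_cover_table(benthic: pd.DataFrame) -> pd.DataFrame:
    """Site-year mean total coral cover (%), excluding CCA and substrate."""
    coral = benthic[~benthic["taxon"].isin(NON_CORAL)]
    per_tr = coral.groupby(["site_id", "year", "transect_id"],
                           observed=True)["cover_pct"].sum().reset_index()
    out = per_tr.groupby(["site_id", "year"],
                         observed=True)["cover_pct"].mean().reset_index()
    return out.rename(columns={"cover_pct": "coral_cover_pct"})


def taxon_cover_table(benthic: pd.DataFrame, year: int) -> pd.DataFrame:
    """Site-level mean percent cover per taxon at one year."""
    sub = benthic[(benthic["year"] == year)
                  & (benthic["taxon"] != BARE_SUBSTRATE)]
    per_tr = sub.groupby(["site_id", "transect_id", "taxon"],
                         observed=True)["cover_pct"].sum().reset_index()
    return (per_tr.groupby(["site_id", "taxon"], observed=True)["cover_pct"]
            .mean().reset_index())


def compute_budgets(benthic: pd.DataFrame, fish: pd.DataFrame,
                    urchins: pd.DataFrame, sponges: pd.DataFrame,
                    substrate: pd.DataFrame, sites: pd.DataFrame,
                    library: RateLibrary | None = None,
                    radius_km: float = 10.0,
                    window_years: int = 8) -> pd.DataFrame:
    """Benthic + fish + static censuses -> site-year budget table."""
    lib = library or load_rate_tables()
    prod = gross_production_table(benthic, lib.taxon_rates)
    years = sorted(benthic["year"].unique())
    ero = bioerosion_table(sites, years, fish, urchins, sponges, substrate,
                           lib, radius_km=radius_km,
                           window_years=window_years)
    budgets = assemble_budgets(prod, ero, sites, porosity=lib.porosity)
    # drop site-years before a site entered the survey
    surveyed = benthic[["site_id", "year"]].drop_duplicates()
    return budgets.merge(surveyed, on=["site_id", "year"])


def run_pipeline(benthic: pd.DataFrame, fish: pd.DataFrame,
                 urchins: pd.DataFrame, sponges: pd.DataFrame,
                 substrate: pd.DataFrame, sites: pd.DataFrame,
                 config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run compute -> trends -> scenarios, writing CSVs + provenance."""
    lib = load_rate_tables(config.rates_path)
    out: dict[str, pd.DataFrame] = {}
    try:
        budgets = compute_budgets(benthic, fish, urchins, sponges, substrate,
                                  sites, lib, config.radius_km,
                                  config.window_years)
        if config.offset_kg:
            budgets = apply_erosion_offset(budgets, config.offset_kg,
                                           lib.porosity)
        out["budgets"] = budgets
    except Exception as exc:  # noqa: BLE001 - re-raise with stage name
        raise RuntimeError(f"pipeline stage 'compute' failed: {exc}") from exc

    try:
        cover = coral_cover_table(benthic)
        out["regional_summary"] = regional_summary(budgets, cover=cover)
        if config.roster:
            out["regional_summary_core"] = regional_summary(
                budgets, roster=config.roster, cover=cover)
        out["percent_positive"] = percent_positive(
            budgets, reference=config.reference, roster=config.roster)
        pairs = budgets.merge(cover, on=["site_id", "year"])
        fits = cover_production_fits(pairs)
        out["thresholds"] = pd.DataFrame([vars(f) for f in fits])
        out["holocene"] = holocene_comparison(out["regional_summary"],
                                              dict(lib.holocene_baselines))
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage 'trends' failed: {exc}") from exc

    if config.scenario_year is not None:
        try:
            year = config.scenario_year
            baseline = budgets[budgets["year"] == year]
            covers = taxon_cover_table(benthic, year)
            frames = []
            for phase_year in sorted({t.phase_year for t in lib.mir_targets}):
                targets = [t for t in lib.mir_targets
                           if t.phase_year == phase_year]
                frames.append(apply_scenario(baseline, covers, targets,
                                             lib.taxon_rates, lib.porosity))
            if config.sweep:
                frames.append(scenario_sweep(baseline, covers, config.sweep,
                                             lib.taxon_rates, lib.porosity))
            out["scenarios"] = pd.concat(frames, ignore_index=True)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"pipeline stage 'scenario' failed: {exc}") from exc

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in out.items():
        write_table(df, out_dir / f"{name}.csv")
    _write_provenance(out_dir, config, out)
    return out


def _write_provenance(out_dir: Path, config: RunConfig,
                      outputs: dict[str, pd.DataFrame]) -> None:
    sidecar = {
        "package": "carbbudget",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "offset_kg": config.offset_kg,
            "radius_km": config.radius_km,
            "window_years": config.window_years,
            "reference": config.reference,
            "scenario_year": config.scenario_year,
        },
        "outputs": {
            name: {
                "rows": len(df),
                "sha256": hashlib.sha256(
                    (out_dir / f"{name}.csv").read_bytes()).hexdigest(),
            } for name, df in outputs.items()
        },
    }
    (out_dir / "provenance.json").write_text(json.dumps(sidecar, indent=2))
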