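"""Gross carbonate production from benthic percent cover.

Production is linear in planar cover: a taxon covering ``c`` percent of the
bottom with an area-normalized calcification rate ``g`` (kg CaCO3 m-2 of
live cover yr-1) produces ``c/100 * g`` kg CaCO3 m-2 yr-1.  Transect totals
are averaged to a site-year mean with a standard error across transects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference_data import TaxonRateTable


@dataclass
class GrossProduction:
    """Site-year gross carbonate production, kg CaCO3 m-2 yr-1."""

    site_id: str
    year: int
    value: float
    se: float
    n_transects: int
    breakdown: dict[str, float] = field(default_factory=dict)
    se_undefined: bool = False  # single transect: SE reported as 0, flagged


def taxon_production(cover_pct: float, g_rate: float) -> float:
    """Production of one taxon: (cover% / 100) x rate."""
    if not 0 <= cover_pct <= 100:
        raise ValueError(f"cover must be in [0, 100] percent, got {cover_pct}")
    return cover_pct / 100.0 * g_rate


def gross_production(cover: pd.DataFrame, rates: TaxonRateTable,
                     site_id: str | None = None,
                     year: int | None = None) -> GrossProduction:
    """Gross production for one site-year from per-transect cover records.

    Parameters
    ----------
    cover
        Columns ``transect_id``, ``taxon``, ``cover_pct`` (one site-year).
        Taxa without a calcification rate (sand, soft corals, ...) are
        treated as non-calcifying and contribute zero.
    rates
        Calcification rate lookup; includes CCA as a producing taxon.
    """
    if cover.empty:
        raise ValueError("gross_production requires at least one transect")
    site_id = site_id if site_id is not None else str(cover["site_id"].iloc[0]) \
        if "site_id" in cover.columns else ""
    year = year if year is not None else int(cover["year"].iloc[0]) \
        if "year" in cover.columns else 0

    transects = cover["transect_id"].unique()
    totals = []
    breakdown_acc: dict[str, list[float]] = {}
    for t in transects:
        sub = cover[cover["transect_id"] == t]
        total = 0.0
        per_taxon: dict[str, float] = {}
        for taxon, c in zip(sub["taxon"], sub["cover_pct"]):
            rate = rates.get(str(taxon))
            if rate is None:
                continue
            p = taxon_production(float(c), rate.g_rate)
            per_taxon[str(taxon)] = per_taxon.get(str(taxon), 0.0) + p
            total += p
        totals.append(total)
        for taxon in rates.taxa():
            breakdown_acc.setdefault(taxon, []).append(per_taxon.get(taxon, 0.0))

    totals_arr = np.asarray(totals, dtype=float)
    n = len(totals_arr)
    value = float(totals_arr.mean())
    se_undefined = n < 2
    se = 0.0 if se_undefined else float(totals_arr.std(ddof=1) / np.sqrt(n))
    breakdown = {t: float(np.mean(v)) for t, v in breakdown_acc.items()
                 if any(x != 0.0 for x in v)}
    return GrossProduction(site_id=site_id, year=year, value=value, se=se,
                           n_transects=n, breakdown=breakdown,
                           se_undefined=se_undefined)


def gross_production_table(benthic: pd.DataFrame,
                           rates: TaxonRateTable) -> pd.DataFrame:
    """Vectorised site-year gross production over a full benthic survey table.

    ``benthic`` columns: site_id, year, transect_id, taxon, cover_pct.
    Returns one row per site-year with ``gross``, ``gross_se``,
    ``n_transects`` plus per-taxon ``prod_<taxon>`` columns.
    """
    df = benthic.copy()
    rate_map = {t: rates[t].g_rate for t in rates.taxa()}
    df["g_rate"] = df["taxon"].map(rate_map)
    unknown = df.loc[df["g_rate"].isna(), "taxon"].unique()
    for taxon in unknown:
        rates.get(str(taxon))  # emits the one-time warning
    df["g_rate"] = df["g_rate"].fillna(0.0)
    if (df["cover_pct"] < 0).any() or (df["cover_pct"] > 100).any():
        raise ValueError("cover_pct outside [0, 100]")
    df["prod"] = df["cover_pct"] / 100.0 * df["g_rate"]

    per_transect = (df.groupby(["site_id", "year", "transect_id"],
                               observed=True)["prod"].sum().reset_index())
    g = per_transect.groupby(["site_id", "year"], observed=True)["prod"]
    out = g.agg(gross="mean", n_transects="count").reset_index()
    sd = g.std(ddof=1).reset_index(name="sd")
    out = out.merge(sd, on=["site_id", "year"])
    out["gross_se"] = (out["sd"] / np.sqrt(out["n_transects"])).fillna(0.0)
    out["se_undefined"] = out["n_transects"] < 2
    out = out.drop(columns="sd")

    # taxon breakdown: mean over transects of per-transect taxon production
    keep = df[df["g_rate"] > 0]
    if not keep.empty:
        bt = (keep.groupby(["site_id", "year", "transect_id", "taxon"],
                           observed=True)["prod"].sum().reset_index())
        n_tr = per_transect.groupby(["site_id", "year"],
                                    observed=True)["transect_id"].nunique()
        bsum = bt.groupby(["site_id", "year", "taxon"],
                          observed=True)["prod"].sum().reset_index()
        bsum = bsum.merge(n_tr.rename("n_tr"), on=["site_id", "year"])
        bsum["prod"] = bsum["prod"] / bsum["n_tr"]
        wide = bsum.pivot_table(index=["site_id", "year"], columns="taxon",
                                values="prod", fill_value=0.0)
        wide.columns = [f"prod_{c}" for c in wide.columns]
        out = out.merge(wide.reset_index(), on=["site_id", "year"], how="left")
        prod_cols = [c for c in out.columns if c.startswith("prod_")]
        out[prod_cols] = out[prod_cols].fillna(0.0)
    return out.sort_values(["site_id", "year"]).reset_index(drop=True)
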