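"""Regionwide summaries of the budget time series.

Annual means are computed over site-level means (each site contributes one
value per year regardless of its transect count), with SE = sd across
sites / sqrt(n).  The cover-production relationship is fit by ordinary
least squares, optionally with site demeaning as a fixed-effect-style
control for site intercepts; the coral-cover threshold for positive net
production is the root -intercept/slope of that line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class ThresholdEstimate:
    slope: float          # kg m-2 yr-1 per percent cover
    slope_se: float
    intercept: float
    intercept_se: float
    threshold_cover: float | None  # percent where predicted net = 0
    n: int
    stratum: str = "all"
    threshold_undefined: bool = False


def regional_summary(budgets: pd.DataFrame,
                     roster: list[str] | None = None,
                     cover: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annual regionwide means +- SE from site-level budgets.

    Parameters
    ----------
    budgets
        Site-year rows with gross, bioerosion_total, net, rap.
    roster
        Optional fixed site subset (e.g. the core sites surveyed every
        year) to remove site-addition artifacts from the series.
    cover
        Optional site-year coral cover (site_id, year, coral_cover_pct) to
        carry along.
    """
    df = budgets
    label = "all sites"
    if roster is not None:
        df = df[df["site_id"].isin(roster)]
        label = f"core-{len(roster)}"
    if cover is not None:
        df = df.merge(cover, on=["site_id", "year"], how="left")

    rows = []
    for year, g in df.groupby("year"):
        if g.empty:
            logger.warning("no sites in year %s; omitted", year)
            continue
        n = len(g)
        row = {"year": int(year), "n_sites": n, "subset": label}
        cols = ["gross", "bioerosion_total", "net", "rap"]
        if cover is not None:
            cols.append("coral_cover_pct")
        for c in cols:
            vals = g[c].to_numpy(dtype=float)
            row[f"{c}_mean"] = float(np.mean(vals))
            row[f"{c}_se"] = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        row["se_undefined"] = n < 2
        rows.append(row)
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def percent_positive(budgets: pd.DataFrame, reference: float = 2.55,
                     roster: list[str] | None = None,
                     lower_bound: bool = False) -> pd.DataFrame:
    """Percent of sites with net > 0 and net >= reference, per year.

    "Positive" is strict (> 0); the reference comparison is inclusive
    (>=, "at least as high as").  With ``lower_bound=True`` the site value
    used is ``net - net_se`` (does the budget's lower uncertainty clear
    the line?).
    """
    df = budgets if roster is None else budgets[budgets["site_id"].isin(roster)]
    rows = []
    for year, g in df.groupby("year"):
        net = g["net"].to_numpy(dtype=float)
        if lower_bound:
            net = net - g["net_se"].to_numpy(dtype=float)
        n = len(net)
        rows.append({
            "year": int(year), "n_sites": n,
            "n_positive": int((net > 0).sum()),
            "pct_positive": 100.0 * (net > 0).mean(),
            "n_above_reference": int((net >= reference).sum()),
            "pct_above_reference": 100.0 * (net >= reference).mean(),
        })
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def cover_production_fit(pairs: pd.DataFrame,
                         demean_by_site: bool = False,
                         stratum: str = "all") -> ThresholdEstimate:
    """OLS fit of net production G against coral cover C (percent).

    ``pairs`` needs columns ``coral_cover_pct`` and ``net`` (and
    ``site_id`` when ``demean_by_site``).  With demeaning, site means are
    removed from both variables before the fit (fixed-effect
    approximation of a site random intercept) and the grand means are
    added back to place the intercept on the original scale.
    """
    df = pairs.dropna(subset=["coral_cover_pct", "net"])
    if len(df) < 3:
        raise ValueError("cover_production_fit requires at least 3 pairs")
    c = df["coral_cover_pct"].to_numpy(dtype=float)
    g = df["net"].to_numpy(dtype=float)
    if demean_by_site:
        cm = df.groupby("site_id")["coral_cover_pct"].transform("mean").to_numpy()
        gm = df.groupby("site_id")["net"].transform("mean").to_numpy()
        c = c - cm + c.mean()
        g = g - gm + g.mean()
    X = sm.add_constant(c)
    fit = sm.OLS(g, X).fit()
    intercept, slope = fit.params
    int_se, slope_se = fit.bse
    undefined = slope <= 0
    threshold = None if undefined else -intercept / slope
    if undefined:
        logger.warning("non-positive cover-production slope; threshold undefined")
    return ThresholdEstimate(slope=float(slope), slope_se=float(slope_se),
                             intercept=float(intercept),
                             intercept_se=float(int_se),
                             threshold_cover=threshold, n=len(df),
                             stratum=stratum, threshold_undefined=undefined)


def cover_production_fits(pairs: pd.DataFrame,
                          period_split: int | None = 2010,
                          by_habitat: bool = False,
                          demean_by_site: bool = False) -> list[ThresholdEstimate]:
    """Period- (and optionally habitat-) stratified cover-production fits.

    ``period_split`` divides the series into [start, split) and
    [split, end] eras, mirroring the pre/post shift in reef-builder
    composition; None fits the pooled data.
    """
    out = []
    groups: list[tuple[str, pd.DataFrame]] = []
    if period_split is None:
        groups.append(("all", pairs))
    else:
        groups.append((f"pre-{period_split}", pairs[pairs["year"] < period_split]))
        groups.append((f"{period_split}-on", pairs[pairs["year"] >= period_split]))
    if by_habitat:
        groups = [(f"{lab}/{hab}", sub)
                  for lab, df in groups
                  for hab, sub in df.groupby("habitat")]
    for lab, df in groups:
        if len(df) >= 3:
            out.append(cover_production_fit(df, demean_by_site=demean_by_site,
                                            stratum=lab))
    return out


def holocene_comparison(summary: pd.DataFrame,
                        baselines: dict[str, float],
                        slr_lines: dict[str, float] | None = None
                        ) -> pd.DataFrame:
    """Tabulate annual regional RAP against geologic accretion baselines.

    Adds one boolean column per baseline period (does that year's mean RAP
    meet or exceed the baseline?) and passes through optional sea-level
    rise reference lines unchanged.
    """
    out = summary[["year", "rap_mean", "rap_se"]].copy()
    for period, rate in baselines.items():
        out[f"baseline_{period}_mm_yr"] = rate
        out[f"exceeds_{period}"] = out["rap_mean"] >= rate
    if slr_lines:
        for name, rate in slr_lines.items():
            out[f"slr_{name}_mm_yr"] = rate
            out[f"keeps_pace_{name}"] = out["rap_mean"] >= rate
    return out
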