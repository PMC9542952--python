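"""Restoration-scenario projections.

A scenario substitutes target percent covers for selected reef-building
taxa at each site's baseline year, holding every other taxon's production
and all erosion components fixed, then recomputes gross, net, and
reef-accretion potential.  Two substitution semantics are used:

* phased restoration targets ("restore to X%"): cover becomes
  ``max(observed, target)``;
* generalized sweeps ("+X% cover"): the increment is added to the
  observed cover.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

import pandas as pd

from .reference_data import (PorosityModel, RestorationTarget, TaxonRateTable)


def _scenario_rows(baseline: pd.DataFrame, covers: pd.DataFrame,
                   new_cover_fn, label: str, rates: TaxonRateTable,
                   porosity: PorosityModel) -> list[dict]:
    rows = []
    calcifying = set(rates.taxa())
    for b in baseline.itertuples():
        site_cov = covers[covers["site_id"] == b.site_id]
        obs = dict(zip(site_cov["taxon"], site_cov["cover_pct"]))
        new = {t: new_cover_fn(t, obs.get(t, 0.0))
               for t in set(obs) | new_cover_fn.taxa}
        total = sum(c for t, c in new.items() if t in calcifying or t in new_cover_fn.taxa)
        if total > 100 + 1e-9:
            raise ValueError(
                f"scenario {label!r} at site {b.site_id!r}: substituted "
                f"calcifying cover sums to {total:.2f}% > 100%")
        delta_gross = sum(
            (new[t] - obs.get(t, 0.0)) / 100.0 * rates[t].g_rate
            for t in new_cover_fn.taxa if t in rates)
        rows.append({
            "site_id": b.site_id, "scenario": label, "baseline_year": b.year,
            "delta_gross": delta_gross,
            "gross": b.gross + delta_gross,
            "net": b.net + delta_gross,
            "rap": (b.net + delta_gross) / porosity.divisor,
            "delta_rap": delta_gross / porosity.divisor,
            "net_se": getattr(b, "net_se", 0.0),
            "rap_se": getattr(b, "net_se", 0.0) / porosity.divisor,
            **{f"cover_{t}": new[t] for t in new_cover_fn.taxa},
        })
    return rows


class _CoverRule:
    def __init__(self, taxa: Mapping[str, float], additive: bool):
        self.taxa = set(taxa)
        self._targets = dict(taxa)
        self._additive = additive

    def __call__(self, taxon: str, observed: float) -> float:
        if taxon not in self._targets:
            return observed
        if self._additive:
            return observed + self._targets[taxon]
        return max(observed, self._targets[taxon])


def apply_scenario(baseline: pd.DataFrame, covers: pd.DataFrame,
                   targets: Iterable[RestorationTarget],
                   rates: TaxonRateTable,
                   porosity: PorosityModel = PorosityModel(),
                   label: str | None = None) -> pd.DataFrame:
    """Project budgets under phased restoration cover targets.

    Parameters
    ----------
    baseline
        Site-year budgets at the baseline year (columns site_id, year,
        gross, net, optionally net_se).
    covers
        Observed site-level mean percent cover (site_id, taxon, cover_pct)
        at the baseline year.
    targets
        Restoration targets sharing one phase year; cover is substituted
        as ``max(observed, target)``.
    """
    targets = list(targets)
    years = {t.phase_year for t in targets}
    if len(years) > 1:
        raise ValueError("apply_scenario expects targets for a single phase year")
    rule = _CoverRule({t.taxon: t.target_cover for t in targets}, additive=False)
    lab = label or f"MIR-{years.pop()}" if years else (label or "scenario")
    return pd.DataFrame(_scenario_rows(baseline, covers, rule, lab, rates, porosity))


def scenario_sweep(baseline: pd.DataFrame, covers: pd.DataFrame,
                   grid: Mapping[str, Iterable[float]],
                   rates: TaxonRateTable,
                   porosity: PorosityModel = PorosityModel(),
                   cartesian: bool = False) -> pd.DataFrame:
    """Generalized "+X% cover" sweeps.

    By default each (taxon, increment) is run as its own scenario; with
    ``cartesian=True`` the full product of per-taxon increments is applied
    jointly.  Results carry ``delta_rap`` for ranking taxa by impact.
    """
    frames = []
    if cartesian:
        taxa = list(grid)
        for combo in itertools.product(*(grid[t] for t in taxa)):
            rule = _CoverRule(dict(zip(taxa, combo)), additive=True)
            lab = "+".join(f"{t}+{c}%" for t, c in zip(taxa, combo))
            frames.append(pd.DataFrame(
                _scenario_rows(baseline, covers, rule, lab, rates, porosity)))
    else:
        for taxon, increments in grid.items():
            for inc in increments:
                rule = _CoverRule({taxon: inc}, additive=True)
                frames.append(pd.DataFrame(_scenario_rows(
                    baseline, covers, rule, f"{taxon}+{inc}%", rates, porosity)))
    return pd.concat(frames, ignore_index=True)
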