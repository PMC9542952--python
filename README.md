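# carbbudget

Census-based coral-reef carbonate budgets for the Florida Keys reef tract.

`carbbudget` turns standard reef-monitoring census data — annual benthic
point-count transects, stationary fish surveys with parrotfish
size-frequency counts, and urchin/sponge/substrate tables — into
site-level carbonate budgets and the regional summaries built on them. It
is written for reef ecologists and carbonate geologists who want a tested,
scriptable alternative to spreadsheet-based budget workflows, and for
restoration planners who need to project how coral-cover targets would
move reef-accretion potential.

## The model

For each site and year:

- **Gross production** `G⁺ = Σᵢ (cᵢ/100)·gᵢ` over coral taxa and crustose
  coralline algae, where `cᵢ` is percent planar cover and `gᵢ` a
  taxon-specific, area-normalized calcification rate
  (kg CaCO₃ m⁻² of live cover yr⁻¹). Transects are averaged to a
  site-year mean ± SE.
- **Bioerosion** is the sum of four components (kg CaCO₃ m⁻² yr⁻¹):
  - *parrotfish*: per fish, bite rate × scar fraction × bite volume ×
    substrate density × foraging hours × 365; summed over a census and
    divided by survey area. Fish surveys are matched to each benthic site
    by habitat, depth band, a 10-km great-circle radius, and a trailing
    8-year window (a running mean).
  - *urchin*: density × E[a·TSᵇ] over an empirical test-size
    distribution (sizes are not recorded by the benthic program).
  - *sponge* and *micro*: linear in occupied sponge area and consolidated
    substrate fraction; static site means replicated across years.
- **Net production** `G = G⁺ − bioerosion` (negative allowed), SEs
  combined in quadrature.
- **Reef-accretion potential** `RAP = G / (ρ·(1−φ))` in mm yr⁻¹, with
  framework porosity φ = 0.63 ± 0.02 and grain density ρ = 2.93 g cm⁻³
  (divisor 1.0841). A geologic **erosion offset** — the gap between
  budget-derived RAP and core-derived accretion over the last millennium,
  1.06 mm yr⁻¹ ≡ 1.15 kg CaCO₃ m⁻² yr⁻¹ — can be subtracted to allow for
  physical and chemical erosion that census budgets miss.
- **Trends and thresholds**: annual regionwide means over site-level
  means, the percent of sites with positive net production (and ≥ the
  2.55 kg m⁻² yr⁻¹ western Atlantic mean), an OLS fit of net production
  against coral cover whose root `−a/b` is the coral-cover threshold for
  positive budgets, and comparisons against Holocene accretion baselines.
- **Restoration scenarios** substitute target covers for reef-building
  taxa (`max(observed, target)` for phased targets, additive increments
  for sweeps), hold erosion fixed, and recompute budgets.

Because the underlying monitoring databases are not redistributable, the
package ships a synthetic reefscape generator that emulates their
structure — 46 sites (a 32-site core from 1996) across four subregions
and three habitats, disturbed by the 1997–98 bleaching, the 2010
cold-water event, 2014/15 bleaching, and the staggered 2017–2019 arrival
of stony coral tissue loss disease — together with a true-state ledger
for parameter-recovery testing.

## Worked example

```python
from carbbudget import (ReefscapeConfig, simulate_reefscape,
                        compute_budgets, accretion_potential,
                        derive_erosion_offset)
from carbbudget.pipeline import coral_cover_table
from carbbudget.trends import regional_summary, percent_positive

data = simulate_reefscape(ReefscapeConfig(seed=0))
budgets = compute_budgets(data.benthic, data.fish, data.urchins,
                          data.sponges, data.substrate, data.sites)
rs = regional_summary(budgets, cover=coral_cover_table(data.benthic))
print(rs[rs.year.isin([1996, 1999, 2010, 2019])]
      [["year", "gross_mean", "net_mean", "rap_mean"]].round(3))
```

```
 year  gross_mean  net_mean  rap_mean
 1996       0.885     0.398     0.367
 1999       0.667     0.194     0.179
 2010       0.567     0.107     0.099
 2019       0.446    -0.018    -0.016
```

Regional mean net production falls in steps after the 1997–98 bleaching
and 2010 cold events and turns negative by 2019 — erosion has overtaken
production on the average simulated reef. On the fixed 32-site core
roster, the share of sites with positive net production declines from
81.25 % (1996) through 56.25 % (1999) to 21.9 % (2019):

```python
core = list(data.sites.loc[data.sites.first_year == 1996, "site_id"])
percent_positive(budgets, roster=core)
```

The conversion operations work on published values directly:

```python
accretion_potential(0.57)          # 0.526 mm/yr  -> prints as 0.53
derive_erosion_offset(1.23, 0.17)  # (1.06 mm/yr, 1.149 kg m-2 yr-1)
```

A command-line interface chains the stages
(`carbbudget simulate | compute | scenario | trends | all`), e.g.:

```sh
carbbudget all --seed 0 --out out/ --offset-kg 1.15 --scenario-year 2019
```

## Input formats

All tables are plain CSV (UTF-8, decimal point, WGS-84 decimal degrees):
`benthic.csv` (site_id, year, transect_id, taxon, cover_pct),
`fish.csv` (survey_id, lat, lon, habitat, depth_m, year, species, phase,
fork_length_cm, count, area_m2), `urchins.csv` (site_id, density_m2),
`sponges.csv` (site_id, species, area_m2_per_m2), `substrate.csv`
(site_id, consolidated_fraction), `sites.csv` (site_id, subregion,
habitat, lat, lon). Rate tables under `src/carbbudget/data/` are packaged
defaults with a provenance column; every one can be overridden by pointing
the loaders (or `--rates`) at a directory of replacement CSVs. See
`docs/methods.md` for the science, parameter defaults, and limitations.
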