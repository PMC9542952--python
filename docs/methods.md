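# Methods

## The budget model

A census-based carbonate budget balances biological carbonate production
against biological erosion; it deliberately omits physical breakage,
sediment export, and chemical dissolution. The package computes, per site
and year:

```
gross  = Σ_taxa (cover_i / 100) · g_i          [kg CaCO3 m-2 yr-1]
net    = gross − (parrotfish + urchin + sponge + micro)
RAP    = net / (ρ · (1 − φ))                   [mm yr-1]
```

Assumptions worth stating explicitly:

- **Planar cover drives production.** Percent cover from point counts is
  used as-is, without rugosity correction; `g_i` is area-normalized to
  planar reef area. Production is therefore exactly linear in cover,
  which the test suite exploits (doubling all covers doubles gross).
- **Site-year means ± SE.** The unit of uncertainty is variation among
  transects (production) or among matched fish surveys (parrotfish
  erosion); SE = sd/√n. Rate-table uncertainty is *not* folded into the
  site SE by default; `rap_se(..., propagate_porosity=True)` adds the
  porosity term by the delta method for sensitivity work. With one
  transect the SE is reported as 0 and flagged undefined.
- **SE of net** combines gross and parrotfish SEs in quadrature; urchin,
  sponge, and micro are static site values with no sampling SE in this
  design.

## Bioerosion components

**Parrotfish.** Individual annual erosion is
`bite_rate · prop_scars · bite_volume · substrate_density ·
foraging_hours · 365 / 1000` (kg yr⁻¹). The benthic program does not
census fish, so fish surveys are matched to each benthic site: identical
habitat class, depth inside that habitat's band (patch 1.8–12.8 m,
offshore shallow 1.8–7.3 m, offshore deep 10.7–16.5 m), great-circle
distance ≤ 10 km (inclusive; spherical earth, R = 6371 km), and survey
year inside a trailing 8-year window ending at the focal year. A
trailing (not centered) window was chosen because early years have no
future data; the window length is configurable. Matched surveys are
weighted equally. When nothing matches, the site receives the mean over
all surveys of its habitat (flagged) rather than zero, to avoid
spuriously positive budgets; a "zero" mode is available.

**Urchin.** Surveys record *Diadema antillarum* density but not test
size, so per-individual erosion is the expectation `E[a · TS^b]` over an
empirical test-size distribution packaged as data. Erosion by
*Echinometra* spp., *Eucidaris tribuloides*, and *Siphonodictyon* spp. is
deliberately omitted (those taxa are outside the survey design); their
presence in inputs is ignored with a warning, never summed.

**Sponge and micro.** Linear in occupied sponge surface area (per
species) and in consolidated-substrate fraction. Both are computed once
per site and replicated across years, because the underlying census
variables were not collected annually; this deliberately suppresses
temporal variability in these terms, and the package accordingly makes no
claims about bioerosion trends.

## The accretion conversion and its grain density

`RAP = net / (ρ(1−φ))` with φ = 0.63 ± 0.02 (regional Holocene framework
porosity) and ρ = 2.93 g cm⁻³. The grain density is not an independent
measurement: it is calibrated so that a single divisor reproduces all
five published (net kg, RAP mm) pairs — (0.57, 0.53), (1.33, 1.23),
(0.22, 0.20), (−1.75, −1.61), (8.06, 7.44). Least squares gives divisor
1.0834 (admissible band 1.083–1.084), i.e. ρ ≈ 2.93 at φ = 0.63, close
to aragonite. The calibration is reproduced in the test suite against an
independent bounded-minimization oracle before the constant is trusted.
Note 8.06/1.0841 = 7.4347, which rounds to 7.43 against the printed
7.44 — the printed input is itself rounded, so the conversion is checked
to ±0.01 mm at the range endpoints.

## The geologic erosion offset

Budget-derived RAP exceeds core-derived accretion because budgets miss
physical and chemical erosion. The offset is derived as
`offset_mm = RAP_budget − rate_core` and converted to mass by the same
divisor: (1.23 − 0.17) mm yr⁻¹ ≡ 1.15 kg CaCO₃ m⁻² yr⁻¹.
`apply_erosion_offset` subtracts the mass offset from net and recomputes
RAP, leaving SEs unchanged (the offset is treated as a fixed scalar, not
a random quantity). Applied to the 2019 mean, 0.22 − 1.15 = −0.93 — note
the adjusted *net* is −0.93 kg m⁻² yr⁻¹ while the adjusted *RAP* is
−0.86 mm yr⁻¹; the two scales are easy to conflate and the package
always reports both columns.

## Trends

Annual regionwide series are means of site-level means (each site counts
once per year), with SE across sites. Because sites were added over time
(six high-cover patch reefs in 2009 distort the all-site series), every
summary can be recomputed on a fixed roster — conventionally the 32-site
core surveyed from 1996.

"Percent positive" uses strict `net > 0`; comparison against the
2.55 kg m⁻² yr⁻¹ western Atlantic reference is inclusive (≥). A
lower-bound mode tests `net − SE > 0` instead.

The coral-cover threshold comes from an OLS fit `G = a + b·C` with
`threshold = −a/b` (undefined and flagged when b ≤ 0). The original
analysis used linear mixed-effects models with temporal autocorrelation;
that machinery is deliberately replaced here by OLS with an optional
site-demeaning mode (a fixed-effects approximation of site random
intercepts), because the threshold's exact value moves with random-effect
and autocorrelation choices. The published 6 % (and offset-adjusted 15 %)
thresholds are therefore treated as qualitative anchors, not exact
targets; both OLS variants are reported. A period split (default
1996–2009 vs 2010–2019) captures the flattening of the cover–production
slope after the 2010 *Orbicella* collapse.

## Restoration scenarios

Phased targets use substitution `max(observed, target)` — "restore this
taxon *to* X %" — while generalized sweeps add increments to observed
cover ("+X %"). Non-target taxa and all erosion components are frozen at
baseline, so `Δnet = Σ (Δcover/100)·g` exactly; a flag exists to scale
parrotfish erosion with cover as a sensitivity extension (off by
default). Scenarios error if substituted calcifying cover would exceed
100 %. With rate tables in which *S. siderea* calcifies 2–3× slower than
the reef-builders, equal cover increments rank
*A. cervicornis* > *A. palmata* > *Orbicella* spp. > *S. siderea* in
ΔRAP, and *S. siderea* increments are proportionally negligible.

## Reference data

All rates are packaged CSVs with a provenance column and are overridable
per table; none are hard-coded. The shipped values are synthetic defaults
at literature magnitudes (the authoritative parameter sets live in
non-redistributable supplements and spreadsheets): taxon calcification
rates ordered *A. cervicornis* (15) > *A. palmata* (12) > *Orbicella*
(10) > ... > *S. siderea* (4) > *P. astreoides* (3.5) > CCA (0.7)
kg m⁻² yr⁻¹; 135 parrotfish parameter rows (9 species × 3 phases × 5
contiguous fork-length classes) tuned so individual erosion spans
~0.005–8 kg yr⁻¹ from small scrapers to large excavators; urchin power
law a = 74 g yr⁻¹ cm⁻ᵇ, b = 1.9 over a 2–9 cm test-size distribution;
sponge rates 2.5–8 kg per m² sponge per yr; micro 0.24 kg m⁻² yr⁻¹ at
full consolidated cover. Foraging time is an explicit field (12 h/day)
so annualization is always transparent. Holocene baselines: mid-Holocene
3.0, late-Holocene 0.5, last-millennium 0.17 mm yr⁻¹. Restoration
targets sum to 14 % (2030) and 23 % (2040) across the three modeled taxa,
inside the 15 %/25 % initiative-wide phase totals (the remainder belongs
to taxa without defined species-level targets).

## The synthetic reefscape

The generator emulates the monitoring design: 46 sites — 32 core sites
(1996) across the Upper/Middle/Lower Keys, 8 Dry Tortugas sites added
2004, 6 patch reefs added 2009 — in three habitats, each with 2–4 ~22-m
transects of 1000-point counts (multinomial; `points_per_transect=None`
gives exact covers). Latent cover follows a multiplicative random walk
(lognormal sd 0.08/yr) around habitat-specific initial means, with
lognormal site-level spread (sd 0.4) and no recovery dynamics. Default
pulse events: 1997–98 bleaching (offshore *A. palmata* ×0.08), a mild
2005 season, the 2010 cold event (Upper/Middle patch *Orbicella* ×0.25),
2014/15 bleaching, and disease staggered Upper 2017 → Middle 2018 →
Lower 2019 (*Orbicella* ×0.55, *S. siderea* ×0.85 per arrival). A slow
*S. siderea* increase (×1.02/yr) mirrors its regional rise. Fish surveys
(176.7 m² stationary cylinders, two per site-year, Poisson counts around
species-specific densities) sit within ~1 km of their site so the 10-km
matching rule is exercised; coordinates are synthetic but metrically
consistent. Initial covers and event multipliers were fixed once so the
simulated region reproduces the documented study conditions — mean
bioerosion ≈ 0.46 with parrotfish + micro > 96 % of the total, ~80 % of
core sites net-positive in 1996, < 60 % by 1999, and well under 40 % by
2019 — and are not tuned per analysis.

What the generator does *not* emulate: mechanistic coral demography and
recovery, larval connectivity, hurricane-driven structural loss,
observer error beyond point-count sampling, spatial autocorrelation of
noise, and the heavy upper tail of real site-level production (no
simulated site reaches the 2.55 kg m⁻² yr⁻¹ reference). Passing tests
on synthetic data therefore demonstrate the *arithmetic and plumbing* of
the pipeline — parameter recovery is exact (≤ 1e-9 relative) on
noise-free runs — not the field accuracy of the rate parameters.

A true-state ledger accompanies every simulation: latent covers, the
gross production they imply, and per-component erosion implied by the
emitted census tables, all computed inside the generator with independent
plain loops (never by calling the pipeline).

## Numerical choices and degenerate inputs

- Matching bounds are inclusive: distance ≤ 10 km, reference comparison
  ≥ 2.55; "positive" is strict > 0.
- Fork-length classes are contiguous half-open bins [min, max), closed
  at the top of the last bin.
- The urchin size pmf is renormalized on load (guarding CSV rounding);
  negative rates, malformed headers, out-of-range covers, and non-positive
  survey areas are hard errors naming the offending column/row.
- Empty fish matches are flagged, not silently zero; empty year groups
  are omitted from summaries with a warning; unknown benthic taxa
  contribute zero production with a once-per-run warning.
- Cover trajectories are rescaled if a site's total live cover would
  exceed 95 %, keeping point-count vectors valid.

## Problem sizes

The default simulation (46 sites × 24 years, ~22k benthic records, ~34k
fish records) runs the full pipeline in well under a minute; the test
suite, including two full simulations and 200 randomized brute-force
oracle censuses, completes in under a minute on one CPU.

## Known limitations

- Packaged rates are magnitude-realistic placeholders; absolute budget
  levels should not be interpreted against real reefs until the rate
  tables are overridden with measured values.
- The OLS threshold is a simplification of a mixed-model quantity; its
  value shifts by a few percentage points of cover under site demeaning.
- Static sponge/micro terms and 8-year fish averaging make the pipeline
  blind to bioerosion trends by construction.
- The geologic offset is a single regional scalar; applying it per site
  ignores habitat differences in physical/chemical erosion.
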