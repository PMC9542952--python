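"""Net carbonate production, reef-accretion potential, and the geologic
erosion offset.

Net production G is gross production minus total bioerosion (kg CaCO3
m-2 yr-1, negative allowed).  Reef-accretion potential (RAP) converts G to
vertical framework growth through the porosity model::

    RAP [mm yr-1] = G / (rho * (1 - phi))

with framework porosity phi = 0.63 and carbonate grain density
rho = 2.93 g cm-3 by default (divisor 1.0841).  RAP is an upper bound on
realized accretion because census budgets omit physical and chemical
erosion; comparing budget-derived RAP against core-derived accretion over
the last millennium yields a single scalar offset (~1.06 mm yr-1, i.e.
1.15 kg CaCO3 m-2 yr-1) that can be subtracted from any budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference_data import PorosityModel


@dataclass
class NetProduction:
    value: float  # kg CaCO3 m-2 yr-1, may be negative
    se: float


def net_production(gross: float, gross_se: float,
                   erosion_total: float,
                   component_ses: tuple[float, ...] = ()) -> NetProduction:
    """G = gross - erosion, with SE combined in quadrature."""
    se = math.sqrt(gross_se ** 2 + sum(s ** 2 for s in component_ses))
    return NetProduction(value=gross - erosion_total, se=se)


def accretion_potential(net, porosity: PorosityModel = PorosityModel()):
    """Convert net production (kg CaCO3 m-2 yr-1) to RAP (mm yr-1).

    Linear and sign-preserving; accepts scalars or arrays.
    """
    return np.asarray(net, dtype=float) / porosity.divisor \
        if np.ndim(net) else float(net) / porosity.divisor


def accretion_to_mass(rap_mm, porosity: PorosityModel = PorosityModel()):
    """Inverse of :func:`accretion_potential`: mm yr-1 back to kg m-2 yr-1."""
    return np.asarray(rap_mm, dtype=float) * porosity.divisor \
        if np.ndim(rap_mm) else float(rap_mm) * porosity.divisor


def rap_se(net_se: float, porosity: PorosityModel = PorosityModel(),
           propagate_porosity: bool = False, net: float = 0.0) -> float:
    """SE of RAP; optionally adds porosity uncertainty (delta method)."""
    base = net_se / porosity.divisor
    if not propagate_porosity:
        return base
    # d(RAP)/d(phi) = net / (rho * (1-phi)^2)
    dphi = abs(net) / (porosity.rho * (1 - porosity.phi) ** 2) * porosity.phi_se
    return math.sqrt(base ** 2 + dphi ** 2)


def derive_erosion_offset(rap_budget_mm: float, core_rate_mm: float,
                          porosity: PorosityModel = PorosityModel()
                          ) -> tuple[float, float]:
    """Offset between budget-derived RAP and core-derived accretion.

    Returns ``(offset_mm, offset_kg)`` where the mass equivalent is
    ``offset_mm * rho * (1 - phi)``.
    """
    offset_mm = rap_budget_mm - core_rate_mm
    return offset_mm, offset_mm * porosity.divisor


def apply_erosion_offset(budgets: pd.DataFrame, offset_kg: float = 1.15,
                         porosity: PorosityModel = PorosityModel()
                         ) -> pd.DataFrame:
    """Subtract a physical/chemical erosion allowance from every budget.

    Adjusts ``net`` by ``-offset_kg`` and recomputes ``rap``; SEs are
    unchanged (the offset is treated as a fixed scalar).
    """
    if offset_kg < 0:
        raise ValueError("offset must be >= 0")
    out = budgets.copy()
    out["net"] = out["net"] - offset_kg
    out["rap"] = out["net"] / porosity.divisor
    return out


def fit_conversion_divisor(net_kg, rap_mm) -> float:
    """Least-squares calibration of the single kg-to-mm divisor.

    Finds ``d`` minimizing ``sum((net/d - rap)^2)`` over printed
    (kg, mm) pairs; closed form d = sum(net^2) / sum(net * rap).
    """
    net = np.asarray(net_kg, dtype=float)
    rap = np.asarray(rap_mm, dtype=float)
    denom = float(np.sum(net * rap))
    if denom == 0:
        raise ValueError("degenerate calibration pairs")
    return float(np.sum(net ** 2)) / denom


def assemble_budgets(production: pd.DataFrame, erosion: pd.DataFrame,
                     sites: pd.DataFrame,
                     porosity: PorosityModel = PorosityModel(),
                     propagate_fish_se: bool = True) -> pd.DataFrame:
    """Join site-year gross production with bioerosion into full budgets.

    Returns one row per site-year: subregion/habitat metadata, gross (+SE),
    the four erosion components, net (+SE, quadrature of gross and
    parrotfish SEs), and rap (+SE).
    """
    keep_prod = production[["site_id", "year", "gross", "gross_se",
                            "n_transects", "se_undefined"]]
    ero_cols = ["site_id", "year", "parrotfish", "parrotfish_se", "urchin",
                "sponge", "micro", "bioerosion_total", "n_fish_surveys",
                "no_fish_data"]
    df = keep_prod.merge(erosion[ero_cols], on=["site_id", "year"], how="inner")
    meta_cols = [c for c in ("site_id", "subregion", "habitat") if c in sites.columns]
    df = df.merge(sites[meta_cols], on="site_id", how="left")

    df["net"] = df["gross"] - df["bioerosion_total"]
    fish_var = df["parrotfish_se"] ** 2 if propagate_fish_se else 0.0
    df["net_se"] = np.sqrt(df["gross_se"] ** 2 + fish_var)
    df["rap"] = df["net"] / porosity.divisor
    df["rap_se"] = df["net_se"] / porosity.divisor
    front = [c for c in ("site_id", "year", "subregion", "habitat") if c in df.columns]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest].sort_values(["site_id", "year"]).reset_index(drop=True)
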