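"""Fixed parameters of the carbonate-budget engine.

All numeric rate values — taxon-specific area-normalized calcification
rates, parrotfish bite parameters, the urchin test-size power law, sponge
and microbioerosion rates, the framework porosity model, Holocene accretion
baselines, and restoration cover targets — are packaged CSV data, never
constants in code.  Every table carries a ``provenance`` column and can be
overridden by pointing a loader at a replacement file or directory.

Units:

* calcification (``g_rate``): kg CaCO3 per m2 of live cover per year
* parrotfish bite parameters: bites h-1, scar fraction, cm3 per scar,
  g CaCO3 cm-3, foraging hours per day
* urchin power law: ``a`` in g CaCO3 individual-1 yr-1 at a 1-cm test,
  ``b`` dimensionless
* sponge / micro rates: kg CaCO3 per m2 (of sponge tissue, or of
  consolidated substrate) per year
* porosity ``phi`` dimensionless, grain density ``rho`` g cm-3
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARROTFISH_SPECIES = (
    "Sparisoma viride",
    "Sparisoma aurofrenatum",
    "Sparisoma rubripinne",
    "Sparisoma chrysopterum",
    "Scarus vetula",
    "Scarus taeniopterus",
    "Scarus iseri",
    "Scarus guacamaia",
    "Scarus coelestinus",
)
PARROTFISH_PHASES = ("juvenile", "initial", "terminal")

#: carbonate producers the default rate table must cover
CORE_TAXA = (
    "Orbicella spp.",
    "Montastraea cavernosa",
    "Siderastrea siderea",
    "Porites astreoides",
    "Colpophyllia natans",
    "Acropora palmata",
    "Acropora cervicornis",
    "CCA",
)

#: bioeroders recorded by other programs but absent from the survey design;
#: their erosion is deliberately omitted from all budgets.
OMITTED_BIOERODERS = (
    "Echinometra lucunter",
    "Echinometra viridis",
    "Eucidaris tribuloides",
    "Siphonodictyon spp.",
)


class RateTableError(ValueError):
    """Raised when a rate table fails validation."""


@dataclass(frozen=True)
class TaxonRate:
    taxon: str
    g_rate: float      # kg CaCO3 m-2 of live cover yr-1
    g_rate_se: float = 0.0


class TaxonRateTable:
    """Lookup of area-normalized calcification rates by taxon."""

    def __init__(self, rates: Iterable[TaxonRate]):
        self._rates: dict[str, TaxonRate] = {}
        for r in rates:
            if r.taxon in self._rates:
                raise RateTableError(f"duplicate taxon rate for {r.taxon!r}")
            if r.g_rate < 0 or r.g_rate_se < 0:
                raise RateTableError(f"negative rate for {r.taxon!r}")
            self._rates[r.taxon] = r
        self._warned: set[str] = set()

    def __len__(self) -> int:
        return len(self._rates)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._rates

    def taxa(self) -> list[str]:
        return list(self._rates)

    def get(self, taxon: str) -> TaxonRate | None:
        """Rate for ``taxon``; None (warn once) for non-calcifying taxa."""
        rate = self._rates.get(taxon)
        if rate is None and taxon not in self._warned:
            self._warned.add(taxon)
            logger.warning(
                "no calcification rate for taxon %r; it contributes zero "
                "production", taxon)
        return rate

    def __getitem__(self, taxon: str) -> TaxonRate:
        try:
            return self._rates[taxon]
        except KeyError:
            raise KeyError(f"no calcification rate for taxon {taxon!r}") from None


@dataclass(frozen=True)
class ParrotfishRate:
    species: str
    phase: str
    length_min: float  # fork length, cm
    length_max: float
    bite_rate: float           # bites h-1
    prop_scars: float          # fraction of bites leaving a scar
    bite_volume: float         # cm3 per scar-leaving bite
    substrate_density: float   # g CaCO3 cm-3
    foraging_hours: float = 12.0

    def __post_init__(self):
        for name in ("bite_rate", "prop_scars", "bite_volume",
                     "substrate_density", "foraging_hours"):
            if getattr(self, name) < 0:
                raise RateTableError(f"negative {name} for {self.species}")
        if self.prop_scars > 1:
            raise RateTableError(f"prop_scars > 1 for {self.species}")


class ParrotfishRateTable:
    """(species, phase, fork-length) -> bite-parameter lookup."""

    def __init__(self, rates: Iterable[ParrotfishRate]):
        self._rates: dict[tuple[str, str], list[ParrotfishRate]] = {}
        seen = set()
        for r in rates:
            key = (r.species, r.phase, r.length_min, r.length_max)
            if key in seen:
                raise RateTableError(f"duplicate parrotfish rate row {key}")
            seen.add(key)
            self._rates.setdefault((r.species, r.phase), []).append(r)
        for rows in self._rates.values():
            rows.sort(key=lambda r: r.length_min)

    def __len__(self) -> int:
        return sum(len(v) for v in self._rates.values())

    def species_phases(self) -> set[tuple[str, str]]:
        return set(self._rates)

    def lookup(self, species: str, phase: str, fork_length: float) -> ParrotfishRate:
        rows = self._rates.get((species, phase))
        if rows is None:
            raise KeyError(
                f"no parrotfish bite parameters for ({species!r}, {phase!r})")
        for i, r in enumerate(rows):
            last = i == len(rows) - 1
            if r.length_min <= fork_length and (fork_length < r.length_max
                                                or (last and fork_length
                                                    <= r.length_max)):
                return r
        raise KeyError(
            f"no parrotfish length class covering {fork_length} cm for "
            f"({species!r}, {phase!r})")


@dataclass(frozen=True)
class UrchinModel:
    """Power-law erosion over an empirical test-size distribution.

    Per-individual annual erosion is E[a * TS^b] over the packaged test-size
    probability mass function (grams), used because surveys record urchin
    density but not test sizes.
    """

    a: float
    b: float
    sizes_cm: tuple[float, ...]
    pmf: tuple[float, ...]

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise RateTableError("urchin power-law constants must be >= 0")
        sizes = np.asarray(self.sizes_cm, dtype=float)
        pmf = np.asarray(self.pmf, dtype=float)
        if sizes.ndim != 1 or sizes.size == 0 or np.any(np.diff(sizes) <= 0):
            raise RateTableError("urchin test-size bins must be strictly increasing")
        if np.any(pmf < 0):
            raise RateTableError("urchin size pmf must be non-negative")
        if abs(pmf.sum() - 1.0) > 1e-9:
            raise RateTableError("urchin size pmf must sum to 1")

    def per_individual_g(self) -> float:
        """Expected erosion per individual, g CaCO3 yr-1."""
        sizes = np.asarray(self.sizes_cm, dtype=float)
        pmf = np.asarray(self.pmf, dtype=float)
        return float(np.sum(pmf * self.a * sizes ** self.b))


@dataclass(frozen=True)
class PorosityModel:
    """Framework porosity / grain density converting mass flux to accretion.

    Net production (kg CaCO3 m-2 yr-1) divided by ``rho * (1 - phi)``
    yields vertical accretion potential in mm yr-1 (the g cm-3 / kg m-2
    unit bookkeeping cancels: 1 kg m-2 over a solid of rho*(1-phi) g cm-3
    is 1/(rho*(1-phi)) mm).
    """

    phi: float = 0.63
    phi_se: float = 0.02
    rho: float = 2.93  # g cm-3

    def __post_init__(self):
        if not 0 <= self.phi < 1:
            raise RateTableError("porosity must satisfy 0 <= phi < 1")
        if self.rho <= 0:
            raise RateTableError("grain density must be positive")

    @property
    def divisor(self) -> float:
        """kg m-2 yr-1 per mm yr-1; 1.0841 at the defaults."""
        return self.rho * (1.0 - self.phi)


@dataclass(frozen=True)
class RestorationTarget:
    taxon: str
    target_cover: float  # percent
    phase_year: int

    def __post_init__(self):
        if not 0 <= self.target_cover <= 100:
            raise RateTableError("target cover must be in [0, 100] percent")


@dataclass
class RateLibrary:
    """Everything fixed the budget engine needs, bundled."""

    taxon_rates: TaxonRateTable
    parrotfish_rates: ParrotfishRateTable
    urchin_model: UrchinModel
    sponge_rates: Mapping[str, float]
    micro_rate: float
    porosity: PorosityModel
    holocene_baselines: Mapping[str, float] = field(default_factory=dict)
    mir_targets: tuple[RestorationTarget, ...] = ()


# ---------------------------------------------------------------------------
# loaders

_DATA_PACKAGE = "carbbudget.data"


def _resolve(name: str, path: str | Path | None) -> Path:
    """Override file if present under ``path``; packaged default otherwise."""
    if path is not None:
        p = Path(path)
        if p.is_file():
            return p
        candidate = p / name
        if candidate.is_file():
            return candidate
    return Path(resources.files(_DATA_PACKAGE) / name)


def _read_csv(name: str, path: str | Path | None, required: list[str]) -> pd.DataFrame:
    fp = _resolve(name, path)
    df = pd.read_csv(fp)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RateTableError(
            f"{fp}: missing required column(s) {', '.join(missing)}")
    digest = hashlib.sha256(fp.read_bytes()).hexdigest()[:12]
    logger.info("loaded %s (%d rows, sha256:%s)", fp, len(df), digest)
    return df


def load_taxon_rates(path: str | Path | None = None) -> TaxonRateTable:
    df = _read_csv("taxon_rates.csv", path, ["taxon", "g_rate"])
    if (df["g_rate"] < 0).any():
        bad = df.loc[df["g_rate"] < 0, "taxon"].iloc[0]
        raise RateTableError(f"negative g_rate for taxon {bad!r}")
    se = df["g_rate_se"] if "g_rate_se" in df.columns else 0.0
    return TaxonRateTable(
        TaxonRate(str(t), float(g), float(s))
        for t, g, s in zip(df["taxon"], df["g_rate"],
                           np.broadcast_to(se, len(df))))


def load_parrotfish_rates(path: str | Path | None = None) -> ParrotfishRateTable:
    cols = ["species", "phase", "length_min_cm", "length_max_cm",
            "bite_rate_hr", "prop_scars", "bite_volume_cm3",
            "substrate_density_g_cm3", "foraging_hours"]
    df = _read_csv("parrotfish_rates.csv", path, cols)
    return ParrotfishRateTable(
        ParrotfishRate(
            species=str(r.species), phase=str(r.phase),
            length_min=float(r.length_min_cm), length_max=float(r.length_max_cm),
            bite_rate=float(r.bite_rate_hr), prop_scars=float(r.prop_scars),
            bite_volume=float(r.bite_volume_cm3),
            substrate_density=float(r.substrate_density_g_cm3),
            foraging_hours=float(r.foraging_hours))
        for r in df.itertuples())


def load_urchin_model(path: str | Path | None = None) -> UrchinModel:
    df = _read_csv("urchin_model.csv", path, ["test_size_cm", "pmf", "a", "b"])
    pmf = df["pmf"].to_numpy(dtype=float)
    if np.any(pmf < 0):
        raise RateTableError("negative pmf value in urchin_model.csv")
    total = pmf.sum()
    if total <= 0:
        raise RateTableError("urchin size pmf sums to zero")
    pmf = pmf / total  # normalize away rounding in the stored weights
    return UrchinModel(
        a=float(df["a"].iloc[0]), b=float(df["b"].iloc[0]),
        sizes_cm=tuple(float(s) for s in df["test_size_cm"]),
        pmf=tuple(float(p) for p in pmf))


def load_sponge_rates(path: str | Path | None = None) -> dict[str, float]:
    df = _read_csv("sponge_rates.csv", path, ["species", "rate_kg_m2_yr"])
    if (df["rate_kg_m2_yr"] < 0).any():
        raise RateTableError("negative rate_kg_m2_yr in sponge_rates.csv")
    return {str(s): float(r) for s, r in zip(df["species"], df["rate_kg_m2_yr"])}


def load_micro_rate(path: str | Path | None = None) -> float:
    df = _read_csv("micro_rate.csv", path, ["rate_kg_m2_yr"])
    rate = float(df["rate_kg_m2_yr"].iloc[0])
    if rate < 0:
        raise RateTableError("negative rate_kg_m2_yr in micro_rate.csv")
    return rate


def load_porosity(path: str | Path | None = None) -> PorosityModel:
    df = _read_csv("porosity.csv", path, ["phi", "phi_se", "rho"])
    row = df.iloc[0]
    return PorosityModel(phi=float(row["phi"]), phi_se=float(row["phi_se"]),
                         rho=float(row["rho"]))


def load_holocene_baselines(path: str | Path | None = None) -> dict[str, float]:
    df = _read_csv("holocene_baselines.csv", path, ["period", "rate_mm_yr"])
    if df["period"].duplicated().any():
        raise RateTableError("duplicate period label in holocene_baselines.csv")
    return {str(p): float(r) for p, r in zip(df["period"], df["rate_mm_yr"])}


def load_mir_targets(path: str | Path | None = None) -> tuple[RestorationTarget, ...]:
    df = _read_csv("mir_targets.csv", path,
                   ["taxon", "target_cover_pct", "phase_year"])
    return tuple(
        RestorationTarget(str(t), float(c), int(y))
        for t, c, y in zip(df["taxon"], df["target_cover_pct"], df["phase_year"]))


def load_rate_tables(path: str | Path | None = None) -> RateLibrary:
    """Load the full rate library.

    Parameters
    ----------
    path
        Directory holding override CSVs.  Any table absent from the
        directory falls back to the packaged default.
    """
    return RateLibrary(
        taxon_rates=load_taxon_rates(path),
        parrotfish_rates=load_parrotfish_rates(path),
        urchin_model=load_urchin_model(path),
        sponge_rates=load_sponge_rates(path),
        micro_rate=load_micro_rate(path),
        porosity=load_porosity(path),
        holocene_baselines=load_holocene_baselines(path),
        mir_targets=load_mir_targets(path),
    )
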