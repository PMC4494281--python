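"""Site configuration loading.

A site TOML bundles the climatology, soil, sward-species, management and
stocking parameters for one location.  Four built-in configurations ship
with the package (``albany``, ``dookie``, ``vasey``, ``wagga``) covering a
temperate kikuyu/subclover system and three Mediterranean phalaris systems.
Herd-energetics and emission-factor defaults live in code and can be
overridden from optional ``[herd]`` / ``[emissions]`` blocks.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

from .climate import ClimateStats
from .ghg import EmissionFactors
from .herd import CalfParams, EnergyParams
from .management import ManagementRules
from .pasture import SoilParams, SpeciesParams

BUILTIN_SITES = ("albany", "dookie", "vasey", "wagga")


@dataclass
class SiteConfig:
    name: str
    latitude: float
    pasture: str  # "kikuyu" | "phalaris"
    stocking_rate: float  # cows/ha
    climate: ClimateStats
    soil: SoilParams
    species: SpeciesParams
    rules: ManagementRules
    energy: EnergyParams = field(default_factory=EnergyParams)
    calf: CalfParams = field(default_factory=CalfParams)
    factors: EmissionFactors = field(default_factory=EmissionFactors)
    initial_mineral_n: float = 15.0  # kg N/ha
    initial_organic_n: float = 400.0
    initial_green: float = 1.2  # t DM/ha
    initial_dead: float = 0.4


def _build(cls, block: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


def load_site(path) -> SiteConfig:
    """Parse and validate a site TOML into a :class:`SiteConfig`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    site = raw["site"]
    clim = dict(raw["climate"])
    clim.setdefault("latitude", site["latitude"])
    clim.setdefault("seasonality_label", site.get("seasonality", "temperate"))
    clim.setdefault("annual_rain_target", float(sum(clim["monthly_rain_mean"])))
    stats = _build(ClimateStats, clim)
    soil = _build(SoilParams, raw["soil"])
    species = _build(SpeciesParams, raw["species"])
    rules = _build(ManagementRules, raw["management"])
    energy = _build(EnergyParams, raw.get("herd", {})) if raw.get("herd") else EnergyParams()
    calf = _build(CalfParams, raw.get("calf", {})) if raw.get("calf") else CalfParams()
    factors = _build(EmissionFactors, raw.get("emissions", {})) if raw.get("emissions") else EmissionFactors()
    init = raw.get("initial", {})
    return SiteConfig(
        name=site["name"],
        latitude=site["latitude"],
        pasture=site["pasture"],
        stocking_rate=site["stocking_rate"],
        climate=stats,
        soil=soil,
        species=species,
        rules=rules,
        energy=energy,
        calf=calf,
        factors=factors,
        **{k: init[k] for k in init},
    )


def builtin_site(name: str) -> SiteConfig:
    """Load one of the shipped site configurations by short name."""
    if name not in BUILTIN_SITES:
        raise ValueError(f"unknown site {name!r}; choose from {BUILTIN_SITES}")
    ref = resources.files("cowcalf").joinpath(f"sites/{name}.toml")
    with resources.as_file(ref) as path:
        return load_site(path)
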