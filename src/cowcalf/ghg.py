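"""Greenhouse-gas accounting for the grazing system.

Sources: enteric fermentation CH4 (feeding-level form of the
Blaxter-Clapperton relation, % of gross energy intake), manure CH4
(proportional to faecal DM), soil N2O (direct from denitrification, indirect
from leached and volatilised N), and embodied emissions of feed production
(pasture, grass silage, bought-in grain).  Results are expressed in CO2
equivalents with 100-year GWPs of 21 (CH4) and 310 (N2O), per hectare and
per kg of calf live weight at weaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

N2O_N_TO_N2O = 44.0 / 28.0


@dataclass
class EmissionFactors:
    gwp_ch4: float = 21.0  # kg CO2-eq/kg CH4 (100-yr)
    gwp_n2o: float = 310.0  # kg CO2-eq/kg N2O (100-yr)
    ge_content: float = 18.4  # MJ gross energy / kg DM
    ch4_energy: float = 55.22  # MJ/kg CH4
    bc_a: float = 1.30  # enteric %GEI intercept
    bc_b: float = 0.112  # %GEI per % digestibility
    bc_c: float = 2.37  # feeding-level intercept
    bc_d: float = 0.050  # feeding-level x digestibility slope
    manure_ch4_per_fecal_dm: float = 0.0019  # kg CH4 / kg faecal DM
    ef_leach: float = 0.0125  # kg N2O-N / kg N leached
    ef_volat: float = 0.010  # kg N2O-N / kg N volatilised
    n2o_fraction_denit: float = 0.015  # N2O-N share of denitrified N
    feed_prod_pasture: float = 14.0  # kg CO2-eq / t DM grazed
    feed_prod_silage: float = 45.0  # kg CO2-eq / t DM fed
    feed_prod_grain: float = 60.0  # kg CO2-eq / t DM fed

    def __post_init__(self) -> None:
        if any(getattr(self, f) < 0 for f in self.__dataclass_fields__):
            raise ValueError("emission factors must be non-negative")


@dataclass
class EmissionLedger:
    """Annual per-hectare emissions by source plus intensity metrics."""

    enteric_ch4_kg: float = 0.0
    enteric_pct_gei: float = 0.0  # intake-weighted annual mean
    enteric_per_ddm: float = 0.0  # g CH4 / kg digestible DM
    manure_ch4_kg: float = 0.0
    n2o_leach_kg: float = 0.0
    n2o_volat_kg: float = 0.0
    n2o_denit_kg: float = 0.0
    feed_prod_co2e_kg: float = 0.0
    total_co2e_kg: float = 0.0
    intensity: float | None = None  # kg CO2-eq / kg calf LW weaned
    shares: dict[str, float] = field(default_factory=dict)

    @property
    def total_co2e_t(self) -> float:
        return self.total_co2e_kg / 1000.0


def enteric_ch4(dmi: float, digestibility: float, feeding_level: float,
                f: EmissionFactors) -> tuple[float, float, float]:
    """Enteric CH4 for one head-day.

    %GEI = a + b*D + L*(c - d*D) with D diet digestibility (%) and L the
    feeding level (multiple of maintenance, floored at 1).  Returns
    (kg CH4/d, % of GEI, g CH4/kg digestible DM).
    """
    if not 40.0 <= digestibility <= 85.0:
        raise ValueError(f"digestibility {digestibility} outside [40, 85]")
    lvl = max(1.0, feeding_level)
    pct_gei = f.bc_a + f.bc_b * digestibility + lvl * (f.bc_c - f.bc_d * digestibility)
    gei = dmi * f.ge_content
    ch4_kg = gei * pct_gei / 100.0 / f.ch4_energy
    ddm = dmi * digestibility / 100.0
    per_ddm = 1000.0 * ch4_kg / ddm if ddm > 0 else 0.0
    return ch4_kg, pct_gei, per_ddm


def manure_ch4(fecal_dm: float, f: EmissionFactors) -> float:
    """Manure CH4, kg/d, from faecal DM (= DMI x (1 - D/100))."""
    if fecal_dm < 0:
        raise ValueError("fecal_dm must be non-negative")
    return fecal_dm * f.manure_ch4_per_fecal_dm


def n2o_from_soil(leach_n: float, volat_n: float, denit_n: float,
                  f: EmissionFactors) -> tuple[float, float, float]:
    """N2O (kg) from soil-N fluxes (kg N): indirect leach/volat EFs, direct
    denitrification fraction; all scaled by 44/28."""
    if min(leach_n, volat_n, denit_n) < 0:
        raise ValueError("N fluxes must be non-negative")
    leach = leach_n * f.ef_leach * N2O_N_TO_N2O
    volat = volat_n * f.ef_volat * N2O_N_TO_N2O
    denit = denit_n * f.n2o_fraction_denit * N2O_N_TO_N2O
    return leach, volat, denit


def feed_production_co2e(pasture_t: float, silage_t: float, grain_t: float,
                         f: EmissionFactors) -> float:
    """Embodied feed-production emissions, kg CO2-eq, linear in the DM masses."""
    return (pasture_t * f.feed_prod_pasture + silage_t * f.feed_prod_silage
            + grain_t * f.feed_prod_grain)


def aggregate(enteric_ch4_kg: float, enteric_pct_gei: float, enteric_per_ddm: float,
              manure_ch4_kg: float, n2o_leach_kg: float, n2o_volat_kg: float,
              n2o_denit_kg: float, feed_prod_co2e_kg: float,
              calf_weaned_kg_per_ha: float | None, f: EmissionFactors
              ) -> EmissionLedger:
    """Assemble the annual ledger: CO2-eq totals, intensity, per-source shares.

    Intensity is undefined (None) when no calf mass was weaned.
    """
    ch4_co2e = f.gwp_ch4 * (enteric_ch4_kg + manure_ch4_kg)
    n2o_co2e = f.gwp_n2o * (n2o_leach_kg + n2o_volat_kg + n2o_denit_kg)
    total = ch4_co2e + n2o_co2e + feed_prod_co2e_kg
    intensity = None
    shares: dict[str, float] = {}
    if calf_weaned_kg_per_ha and calf_weaned_kg_per_ha > 0 and total > 0:
        intensity = total / calf_weaned_kg_per_ha
        shares = {
            "enteric": f.gwp_ch4 * enteric_ch4_kg / total,
            "manure_soil": (f.gwp_ch4 * manure_ch4_kg + n2o_co2e) / total,
            "feed_production": feed_prod_co2e_kg / total,
        }
    return EmissionLedger(
        enteric_ch4_kg=enteric_ch4_kg,
        enteric_pct_gei=enteric_pct_gei,
        enteric_per_ddm=enteric_per_ddm,
        manure_ch4_kg=manure_ch4_kg,
        n2o_leach_kg=n2o_leach_kg,
        n2o_volat_kg=n2o_volat_kg,
        n2o_denit_kg=n2o_denit_kg,
        feed_prod_co2e_kg=feed_prod_co2e_kg,
        total_co2e_kg=total,
        intensity=intensity,
        shares=shares,
    )
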