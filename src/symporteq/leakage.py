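"""Metabolite-leakage mass balance for dilute cultures.

At typical laboratory or environmental biomass densities the intracellular
compartment is a vanishing fraction of the culture volume (about 2 mL of
cell volume per gram of yeast biomass).  When a reversible electroneutral
symporter equilibrates a metabolite across the plasma membrane, almost the
entire metabolite pool therefore ends up in the medium: at dpH = 0 and
100 mg/L biomass, 1 mM intracellular pyruvate partitions into 0.2 umol
inside the cells versus 1 mmol (88 mg, 88% of the cell dry mass) outside.
This module does that bookkeeping for arbitrary geometries and gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

from .thermo import TransmembraneState, WeakAcid

__all__ = [
    "CultureGeometry",
    "PartitionResult",
    "intracellular_volume_fraction",
    "equilibrium_partition",
]


@dataclass(frozen=True)
class CultureGeometry:
    """Culture volume bookkeeping.

    Parameters
    ----------
    biomass_concentration
        Dry biomass per culture volume, g/L.
    specific_intracellular_volume
        Intracellular volume per gram dry biomass, mL/g (default 2).
    culture_volume
        Working volume of the culture, L (default 1).
    """

    biomass_concentration: float
    specific_intracellular_volume: float = 2.0
    culture_volume: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "biomass_concentration",
            "specific_intracellular_volume",
            "culture_volume",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def intracellular_volume(self) -> float:
        """Total intracellular volume in litres."""
        return (
            self.biomass_concentration
            * self.specific_intracellular_volume
            * 1e-3
            * self.culture_volume
        )


@dataclass(frozen=True)
class PartitionResult:
    """Equilibrium partition of a metabolite between biomass and medium."""

    intracellular_amount_umol: float
    extracellular_amount_mmol: float
    extracellular_mass_mg: float
    mass_fraction_of_biomass_pct: float


def intracellular_volume_fraction(geometry: CultureGeometry) -> float:
    """Intracellular volume as a percentage of the culture volume.

    100 mg/L of biomass at 2 mL/g occupies just 0.02% of the culture.
    """
    return 100.0 * geometry.intracellular_volume / geometry.culture_volume


def equilibrium_partition(
    c_in: float,
    state: TransmembraneState,
    geometry: CultureGeometry,
    acid: WeakAcid,
    exact_volume: bool = False,
) -> PartitionResult:
    """Partition a metabolite pool at symport equilibrium.

    The extracellular concentration is c_in / 10**dpH; amounts follow from
    the compartment volumes.  By default the extracellular volume is
    approximated by the full culture volume (the intracellular fraction is
    ~0.02% in the reference scenario); ``exact_volume=True`` subtracts the
    intracellular volume instead.

    Parameters
    ----------
    c_in
        Intracellular concentration, mM.
    state
        Transmembrane pH state (only dpH matters).
    geometry
        Culture geometry.
    acid
        Transported acid; its molar mass converts amounts to mass.

    Returns
    -------
    PartitionResult
        Amounts in umol (inside) and mmol (outside), the extracellular
        mass in mg, and that mass as a percentage of the dry biomass.
    """
    if c_in < 0:
        raise ValueError(f"c_in={c_in} must be >= 0")
    v_in = geometry.intracellular_volume
    v_out = geometry.culture_volume - v_in if exact_volume else geometry.culture_volume
    c_out = c_in / 10.0**state.delta_pH
    intracellular_mmol = c_in * v_in
    extracellular_mmol = c_out * v_out
    mass_mg = extracellular_mmol * acid.molar_mass
    biomass_mg = geometry.biomass_concentration * geometry.culture_volume * 1000.0
    return PartitionResult(
        intracellular_amount_umol=intracellular_mmol * 1000.0,
        extracellular_amount_mmol=extracellular_mmol,
        extracellular_mass_mg=mass_mg,
        mass_fraction_of_biomass_pct=100.0 * mass_mg / biomass_mg,
    )
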