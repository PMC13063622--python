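"""Equilibrium thermodynamics of electroneutral monocarboxylate/H+ symport.

A secondary transporter that co-translocates one proton per monovalent
carboxylate anion moves no net charge across the membrane, so of the two
components of the proton motive force only the pH gradient
(dpH = pH_in - pH_out) contributes to the driving force.  At transport
equilibrium the anion therefore distributes according to

    [A-]_in / [A-]_out = 10**dpH

Weak-acid speciation (Henderson-Hasselbalch) converts between the anion
ratio and the ratio of total acid (anion + undissociated form); for acids
whose pKa lies far below both pH values the two ratios coincide.

All concentrations in this layer are mM; energies are kJ/mol; the gas
constant is R = 8.314 J/(mol K) and the default temperature 303.15 K
(cultures at 30 degrees C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import UnsupportedStoichiometryError

__all__ = [
    "R_GAS",
    "TransmembraneState",
    "WeakAcid",
    "SymportStoichiometry",
    "LACTIC_ACID",
    "PYRUVIC_ACID",
    "anion_accumulation_ratio",
    "anion_fraction",
    "total_accumulation_ratio",
    "equilibrium_external_concentration",
    "symport_driving_force",
]

#: Gas constant, J mol-1 K-1.
R_GAS = 8.314


@dataclass(frozen=True)
class TransmembraneState:
    """pH and electrical state of the two compartments.

    Parameters
    ----------
    pH_in, pH_out
        Cytosolic and extracellular pH.  Must lie in [0, 14].
    delta_psi
        Membrane potential (inside minus outside) in volts.  Stored for
        completeness and validated, but never used by the equilibrium
        formulas: electroneutral symport is insensitive to it.
    temperature
        Absolute temperature in kelvin (default 303.15 K, i.e. 30 C).
    """

    pH_in: float
    pH_out: float
    delta_psi: float = 0.0
    temperature: float = 303.15

    def __post_init__(self) -> None:
        for name in ("pH_in", "pH_out"):
            value = getattr(self, name)
            if not 0.0 <= value <= 14.0:
                raise ValueError(f"{name}={value} outside [0, 14]")
        if not self.temperature > 0:
            raise ValueError(f"temperature={self.temperature} must be > 0")

    @property
    def delta_pH(self) -> float:
        """Transmembrane pH gradient, pH_in - pH_out."""
        return self.pH_in - self.pH_out


@dataclass(frozen=True)
class WeakAcid:
    """A monocarboxylic acid identified by its pKa and molar mass (g/mol)."""

    name: str
    pKa: float
    molar_mass: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pKa < 14.0:
            raise ValueError(f"pKa={self.pKa} outside (0, 14)")
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass={self.molar_mass} must be > 0")


#: Lactic acid, pKa 3.86.
LACTIC_ACID = WeakAcid("lactate", pKa=3.86, molar_mass=90.08)
#: Pyruvic acid, pKa 2.50.
PYRUVIC_ACID = WeakAcid("pyruvate", pKa=2.50, molar_mass=88.06)


@dataclass(frozen=True)
class SymportStoichiometry:
    """Coupling stoichiometry of the symporter.

    ``protons`` H+ are co-transported with one substrate molecule of
    charge ``substrate_charge``.  The transport step is electroneutral
    iff protons + substrate_charge == 0, the only mode modelled here.
    """

    protons: int = 1
    substrate_charge: int = -1

    def __post_init__(self) -> None:
        if self.protons < 1:
            raise ValueError("protons must be >= 1")

    @property
    def is_electroneutral(self) -> bool:
        return self.protons + self.substrate_charge == 0


_DEFAULT_STOICH = SymportStoichiometry()


def _require_electroneutral(stoich: SymportStoichiometry) -> None:
    if not stoich.is_electroneutral:
        raise UnsupportedStoichiometryError(
            f"stoichiometry {stoich.protons} H+ : charge {stoich.substrate_charge} "
            "is not electroneutral; charged symport is not modelled"
        )


def anion_accumulation_ratio(
    state: TransmembraneState,
    stoich: SymportStoichiometry = _DEFAULT_STOICH,
) -> float:
    """Equilibrium in/out ratio of the transported anion, 10**(n_H * dpH).

    Greater than 1 exactly when dpH > 0 (accumulative uptake); less than
    1 when the outside is more alkaline than the cytosol, in which case
    equilibrium lies on the side of net export.
    """
    _require_electroneutral(stoich)
    return 10.0 ** (stoich.protons * state.delta_pH)


def anion_fraction(acid: WeakAcid, pH: float) -> float:
    """Fraction of total acid present as the anion at the given pH.

    Henderson-Hasselbalch speciation: 1 / (1 + 10**(pKa - pH)).
    Monotonically increasing in pH; 0.5 at pH == pKa.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH={pH} outside [0, 14]")
    return 1.0 / (1.0 + 10.0 ** (acid.pKa - pH))


def total_accumulation_ratio(
    state: TransmembraneState,
    acid: WeakAcid,
    stoich: SymportStoichiometry = _DEFAULT_STOICH,
) -> float:
    """Equilibrium in/out ratio of total acid (anion + undissociated).

    The anion equilibrates at 10**dpH; dividing each side's anion
    concentration by its anion fraction gives

        R_total = 10**dpH * (1 + 10**(pKa - pH_in)) / (1 + 10**(pKa - pH_out))

    which approaches the pure anion ratio when pKa << min(pH_in, pH_out).
    For lactic acid (pKa 3.86) between pH_out 5 and pH_in 7 this corrects
    the 100-fold anion ratio down to ~93-fold.
    """
    _require_electroneutral(stoich)
    ar = anion_accumulation_ratio(state, stoich)
    return ar * (1.0 + 10.0 ** (acid.pKa - state.pH_in)) / (
        1.0 + 10.0 ** (acid.pKa - state.pH_out)
    )


def equilibrium_external_concentration(
    c_in: float, state: TransmembraneState
) -> float:
    """Extracellular anion concentration (mM) at equilibrium for fixed c_in.

    c_out = c_in / 10**dpH.  As the extracellular pH rises toward and past
    the cytosolic pH, holding the intracellular concentration constant
    requires an ever higher extracellular concentration.
    """
    if c_in < 0:
        raise ValueError(f"c_in={c_in} must be >= 0")
    return c_in / anion_accumulation_ratio(state)


def symport_driving_force(
    state: TransmembraneState,
    c_in: float,
    c_out: float,
    stoich: SymportStoichiometry = _DEFAULT_STOICH,
) -> float:
    """Gibbs free energy of inward symport, kJ per mol substrate.

    dG = RT * [ln(c_in/c_out) - n_H * ln(10) * dpH]

    Negative values mean net inward transport is thermodynamically
    favourable; zero exactly at c_in/c_out == 10**(n_H * dpH).
    """
    _require_electroneutral(stoich)
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be > 0")
    rt = R_GAS * state.temperature
    return (
        rt
        * (math.log(c_in / c_out) - stoich.protons * math.log(10.0) * state.delta_pH)
        / 1000.0
    )
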