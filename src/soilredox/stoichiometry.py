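"""Half-reaction registry, chlorophenol ladder and per-bottle unit conversions.

Anaerobic respiration funnels electrons from a limited donor pool to
competing terminal electron acceptors (TEAs): Fe(III), sulfate, CO2
(methanogenesis) and, in chlorophenol-polluted soil, the chlorinated
aromatic itself.  Every TEA is described by a balanced half reaction with a
fixed number of electron equivalents (eeq) per mole of compound turned
over, so measured endpoint concentrations can be converted to a common
currency of micromoles of electrons per incubation bottle.

This module holds:

* the half-reaction registry (loaded from ``data/half_reactions.yaml``,
  user-extensible),
* the chlorophenol dechlorination ladder PCP -> TeCP -> TCP -> DCP, where
  each Cl->H substitution consumes 2 electrons,
* the bottle geometry of the incubation (15 g soil, 30 mL water, 150 mL
  serum bottle) and the unit conversions from measured concentrations
  (ug/g, mg/g soil; permil of headspace gas) to micromoles per bottle.

The headspace gas basis deserves a note: methane is measured in permil of
the headspace gas, and the conversion to moles requires a total-gas basis.
The default of 1000 umol per bottle is a *calibrated* constant chosen so
that permil values map 1:1 onto umol of CH4 (a physical 1-atm, 25 degC
headspace of ~114 mL would hold ~4.7 mmol of gas).  It is configurable via
:class:`BottleGeometry`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "HalfReaction",
    "HalfReactionRegistry",
    "ChlorophenolSpecies",
    "BottleGeometry",
    "Measurement",
    "Unit",
    "MOLAR_MASS",
    "load_registry",
    "eeq_per_mol",
    "dechlorination_eeq",
    "mass_to_micromoles",
    "micromoles_to_mass",
    "permil_to_micromoles",
    "micromoles_to_permil",
    "RegistryError",
    "UnitError",
]

#: IUPAC molar masses (g/mol) of the budgeted analytes.
MOLAR_MASS: dict[str, float] = {
    "Fe": 55.845,
    "SO4": 96.06,
    "CH4": 16.04,
    "PCP": 266.34,
    "TeCP": 231.89,
    "TCP": 197.45,
    "DCP": 163.00,
}


class RegistryError(KeyError):
    """Unknown half-reaction couple requested from the registry."""


class UnitError(ValueError):
    """A conversion was asked for a measurement in an incompatible unit."""


class Unit(str, enum.Enum):
    """Measurement units appearing in the endpoint tables."""

    ug_per_g = "ug_per_g"
    mg_per_g = "mg_per_g"
    permil_headspace = "permil_headspace"
    mg_per_kg = "mg_per_kg"
    mV = "mV"
    pH_unit = "pH_unit"


#: Units that denote a (non-negative) concentration.
_CONCENTRATION_UNITS = {
    Unit.ug_per_g,
    Unit.mg_per_g,
    Unit.permil_headspace,
    Unit.mg_per_kg,
}


@dataclass(frozen=True)
class HalfReaction:
    """One redox couple and its electron-equivalent bookkeeping.

    ``electrons_per_mole`` is the eeq value used for budgeting;
    ``electrons_transferred`` is the electron count of the written half
    reaction (they differ only for disproportionations such as
    acetoclastic methanogenesis, where no free electrons appear).
    """

    name: str
    oxidized_species: str
    reduced_species: str
    electrons_per_mole: int
    protons: int
    charge_oxidized: int
    charge_reduced: int
    reference_note: str = ""
    electrons_transferred: int | None = None

    def __post_init__(self) -> None:
        if self.electrons_per_mole < 1:
            raise ValueError(f"{self.name}: electrons_per_mole must be >= 1")
        if self.electrons_transferred is None:
            object.__setattr__(self, "electrons_transferred", self.electrons_per_mole)

    def charge_balanced(self) -> bool:
        """Check q_ox + protons - e == q_red for the written half reaction."""
        return (
            self.charge_oxidized + self.protons - self.electrons_transferred
            == self.charge_reduced
        )


class HalfReactionRegistry(dict):
    """Mapping couple-name -> :class:`HalfReaction` with validation."""

    def __missing__(self, key):  # noqa: D105
        raise RegistryError(
            f"unknown half-reaction couple {key!r}; known couples: "
            f"{sorted(self)}"
        )

    @classmethod
    def from_mapping(cls, raw: dict) -> "HalfReactionRegistry":
        reg = cls()
        for name, entry in raw.items():
            hr = HalfReaction(name=name, **entry)
            if not hr.charge_balanced():
                raise ValueError(f"half reaction {name!r} is not charge balanced")
            reg[name] = hr
        return reg


def load_registry(path: str | Path | None = None) -> HalfReactionRegistry:
    """Load the half-reaction registry from YAML.

    With no ``path`` the packaged default registry is used.  Users may
    point at their own YAML file to add couples.
    """
    if path is None:
        text = (
            resources.files("soilredox").joinpath("data/half_reactions.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return HalfReactionRegistry.from_mapping(yaml.safe_load(text))


_DEFAULT_REGISTRY: HalfReactionRegistry | None = None


def default_registry() -> HalfReactionRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


def eeq_per_mol(couple: str, registry: HalfReactionRegistry | None = None) -> int:
    """Electron equivalents transferred per mole of compound for ``couple``."""
    reg = registry if registry is not None else default_registry()
    return reg[couple].electrons_per_mole


class ChlorophenolSpecies(enum.Enum):
    """The reductive-dechlorination ladder of pentachlorophenol.

    Each step replaces one ring chlorine with hydrogen (2 electrons) and
    drops the molar mass by ~34.44 g/mol (Cl -> H).
    """

    PCP = ("PCP", 5, MOLAR_MASS["PCP"])
    TeCP_2345 = ("2,3,4,5-TeCP", 4, MOLAR_MASS["TeCP"])
    TCP_345 = ("3,4,5-TCP", 3, MOLAR_MASS["TCP"])
    DCP_35 = ("3,5-DCP", 2, MOLAR_MASS["DCP"])

    def __init__(self, label: str, chlorine_count: int, molar_mass: float):
        self.label = label
        self.chlorine_count = chlorine_count
        self.molar_mass = molar_mass


def dechlorination_eeq(source: ChlorophenolSpecies, product: ChlorophenolSpecies) -> int:
    """Electrons consumed converting ``source`` to ``product`` (2 per Cl removed).

    Raises ``ValueError`` if ``product`` is more chlorinated than ``source``.
    """
    dcl = source.chlorine_count - product.chlorine_count
    if dcl < 0:
        raise ValueError(
            f"{product.label} is more chlorinated than {source.label}: "
            "dechlorination only removes chlorines"
        )
    return 2 * dcl


@dataclass(frozen=True)
class BottleGeometry:
    """Physical set-up of one incubation bottle.

    ``headspace_gas_basis`` is the total micromoles of headspace gas used
    to convert permil readings to moles; the default 1000 umol is a
    calibration constant (see module docstring), not a physical volume.
    """

    soil_mass: float = 15.0  # g air-dry soil
    water_volume: float = 30.0  # mL
    bottle_volume: float = 150.0  # mL
    headspace_gas_basis: float = 1000.0  # umol total gas
    temperature: float = 25.0  # degC

    def __post_init__(self) -> None:
        for name in ("soil_mass", "water_volume", "bottle_volume",
                     "headspace_gas_basis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.water_volume >= self.bottle_volume:
            raise ValueError("water_volume must be smaller than bottle_volume")


@dataclass(frozen=True)
class Measurement:
    """A single analyte reading with its unit."""

    analyte: str
    value: float
    unit: Unit

    def __post_init__(self) -> None:
        if self.unit in _CONCENTRATION_UNITS and self.value < 0:
            raise ValueError(
                f"{self.analyte}: concentration in {self.unit.value} cannot be "
                f"negative (got {self.value})"
            )


def mass_to_micromoles(
    conc: Measurement, geometry: BottleGeometry, molar_mass: float
) -> float:
    """Convert a soil mass concentration to micromoles per bottle.

    ug/g: value * soil_mass / molar_mass; mg/g carries a factor 1000.
    """
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    if conc.unit is Unit.ug_per_g:
        return conc.value * geometry.soil_mass / molar_mass
    if conc.unit is Unit.mg_per_g:
        return conc.value * geometry.soil_mass * 1000.0 / molar_mass
    raise UnitError(
        f"cannot convert {conc.analyte} in unit {conc.unit.value} to micromoles"
    )


def micromoles_to_mass(
    umol: float, geometry: BottleGeometry, molar_mass: float, unit: Unit = Unit.mg_per_g
) -> float:
    """Inverse of :func:`mass_to_micromoles` (used by the simulator)."""
    if unit is Unit.ug_per_g:
        return umol * molar_mass / geometry.soil_mass
    if unit is Unit.mg_per_g:
        return umol * molar_mass / (geometry.soil_mass * 1000.0)
    raise UnitError(f"cannot express micromoles in unit {unit.value}")


def permil_to_micromoles(conc: Measurement, geometry: BottleGeometry) -> float:
    """Convert a permil-of-headspace gas reading to micromoles per bottle."""
    if conc.unit is not Unit.permil_headspace:
        raise UnitError(
            f"{conc.analyte}: permil conversion requires unit permil_headspace, "
            f"got {conc.unit.value}"
        )
    if not 0.0 <= conc.value <= 1000.0:
        raise ValueError(f"permil value out of range [0, 1000]: {conc.value}")
    return conc.value / 1000.0 * geometry.headspace_gas_basis


def micromoles_to_permil(umol: float, geometry: BottleGeometry) -> float:
    """Inverse of :func:`permil_to_micromoles`."""
    return umol / geometry.headspace_gas_basis * 1000.0
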