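"""Physical constants, energy units, and rounding conventions.

Two conversion registries are provided.  ``codata`` carries full-precision
CODATA-2018 factors and is the default everywhere.  ``paper`` replaces the
kJ/mol -> cm^-1 factor by the rounded 83.59 commonly printed in
thermochemistry tables, so that numbers quoted at that precision can be
reproduced bit-for-bit.  All derived constants (Boltzmann constant in
cm^-1/K, the inertia-to-rotational-constant factor, ...) are computed once
at registry construction and frozen; no other module embeds a literal
conversion factor.

The package's canonical working unit for relative energies is cm^-1, the
natural unit of rotational/vibrational spectroscopy.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ConstantsRegistry",
    "EnergyQuantity",
    "convert_energy",
    "get_registry",
    "round_half_away",
]

# Exact SI defining constants (2019 redefinition) and CODATA-2018 values.
_PLANCK_J_S = 6.62607015e-34            # h, exact
_LIGHT_M_S = 2.99792458e8               # c, exact
_BOLTZMANN_J_K = 1.380649e-23           # k_B, exact
_AVOGADRO = 6.02214076e23               # N_A, exact
_AMU_KG = 1.66053906660e-27             # unified atomic mass unit
_HARTREE_J = 4.3597447222071e-18        # E_h

_UNIT_ALIASES = {
    "hartree": "hartree",
    "eh": "hartree",
    "au": "hartree",
    "cm-1": "cm-1",
    "cm^-1": "cm-1",
    "wavenumber": "cm-1",
    "kj/mol": "kJ/mol",
    "kjmol": "kJ/mol",
    "kj mol-1": "kJ/mol",
}


def _canonical_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unsupported energy unit {unit!r}; supported: hartree, cm-1, kJ/mol"
        ) from None


class ConstantsRegistry:
    """Frozen bundle of physical constants and unit-conversion factors.

    Parameters
    ----------
    name : {"codata", "paper"}
        ``codata`` uses full-precision factors; ``paper`` pins the
        kJ/mol -> cm^-1 factor to the rounded 83.59.
    """

    def __init__(self, name: str = "codata"):
        if name not in ("codata", "paper"):
            raise ValueError(f"unknown constants registry {name!r}")
        self.name = name
        hc_cm = _PLANCK_J_S * _LIGHT_M_S * 100.0  # J per cm^-1
        self.hartree_to_cm = _HARTREE_J / hc_cm
        if name == "paper":
            self.kjmol_to_cm = 83.59
        else:
            self.kjmol_to_cm = 1000.0 / _AVOGADRO / hc_cm
        #: Boltzmann constant in cm^-1 / K (0.6950348...)
        self.k_B_cm = _BOLTZMANN_J_K / hc_cm
        #: B [MHz] = rot_MHz_amu_A2 / I [amu Angstrom^2]  (505379.0...)
        self.rot_MHz_amu_A2 = _PLANCK_J_S / (8.0 * math.pi**2 * _AMU_KG * 1e-20) / 1e6
        # raw SI values, exposed for the statistical-mechanics expressions
        self.h_J_s = _PLANCK_J_S
        self.c_m_s = _LIGHT_M_S
        self.k_B_J_K = _BOLTZMANN_J_K
        self.amu_kg = _AMU_KG
        self.standard_pressure_Pa = 1.0e5  # 1 bar standard state
        self._to_cm = {
            "cm-1": 1.0,
            "hartree": self.hartree_to_cm,
            "kJ/mol": self.kjmol_to_cm,
        }
        self._frozen = True

    def __setattr__(self, key, value):
        if getattr(self, "_frozen", False):
            raise AttributeError("ConstantsRegistry is immutable after construction")
        super().__setattr__(key, value)

    def factor_to_cm(self, unit: str) -> float:
        return self._to_cm[_canonical_unit(unit)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ConstantsRegistry(name={self.name!r})"


_REGISTRIES: dict[str, ConstantsRegistry] = {}


def get_registry(name: str = "codata") -> ConstantsRegistry:
    """Return the shared registry instance for *name* (constructed once)."""
    if name not in _REGISTRIES:
        _REGISTRIES[name] = ConstantsRegistry(name)
    return _REGISTRIES[name]


@dataclasses.dataclass(frozen=True)
class EnergyQuantity:
    """An energy value together with its unit (hartree, cm-1 or kJ/mol)."""

    value: float
    unit: str = "cm-1"

    def __post_init__(self):
        object.__setattr__(self, "unit", _canonical_unit(self.unit))

    def to(self, target_unit: str, registry: ConstantsRegistry | None = None) -> "EnergyQuantity":
        return convert_energy(self, target_unit, registry)

    def in_cm(self, registry: ConstantsRegistry | None = None) -> float:
        """The bare value expressed in the canonical unit cm^-1."""
        return convert_energy(self, "cm-1", registry).value


def convert_energy(
    q: EnergyQuantity,
    target_unit: str,
    registry: ConstantsRegistry | None = None,
) -> EnergyQuantity:
    """Convert *q* to *target_unit* through the registry's frozen factors.

    Conversion goes through cm^-1 as the pivot; any chain of conversions is
    therefore equivalent to the direct one up to floating-point rounding
    (well within the 1e-10 relative round-trip guarantee).
    """
    registry = registry or get_registry()
    target = _canonical_unit(target_unit)
    if q.unit == target:
        return EnergyQuantity(q.value, target)
    in_cm = q.value * registry.factor_to_cm(q.unit)
    return EnergyQuantity(in_cm / registry.factor_to_cm(target), target)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's ``round`` uses banker's rounding; spectroscopy tables round
    3877.55 -> 3877.6, so comparisons against printed values use this rule.
    """
    q = Decimal("1") if ndigits == 0 else Decimal(f"1e-{ndigits}")
    d = Decimal(repr(float(x)))
    if d < 0:
        return float(-((-d).quantize(q, rounding=ROUND_HALF_UP)))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))
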