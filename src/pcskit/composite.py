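"""Composite electronic-energy assembly.

The composite recipe implemented here approximates a near-CBS, core-correlated
coupled-cluster energy as three additive pieces::

    E_total = E_base[CCSD(T)-F12/3F12, fc]  +  dCBS  +  dCV

where

* ``dCBS`` is the complete-basis-set correction obtained from the standard
  two-point n^-3 extrapolation of MP2-F12 energies at basis cardinals 3 and 4,
  minus the MP2-F12 energy at the base basis, and
* ``dCV`` is the core-valence correction: all-electron minus frozen-core
  MP2-F12 energy in a core-correlating basis.

Whether the extrapolation acts on total energies or only on the correlation
component is the caller's choice; the chosen mode travels with the result as
metadata so provenance stays honest (the printed correction columns of
published tables are consumed identically either way).
"""

from __future__ import annotations

import dataclasses

from .units import ConstantsRegistry, EnergyQuantity, get_registry

__all__ = [
    "LevelEnergyRecord",
    "CompositeEnergyBreakdown",
    "cbs_two_point",
    "cbs_correction",
    "cv_correction",
    "pcs_total",
    "relative_energies",
]


@dataclasses.dataclass(frozen=True)
class LevelEnergyRecord:
    """One species x one level-of-theory electronic energy."""

    species_id: str
    level: str                       # e.g. "CC-F12/3F12", "MP2-F12/4F12"
    core_treatment: str              # "frozen-core" | "all-electron"
    energy: EnergyQuantity

    def __post_init__(self):
        if self.core_treatment not in ("frozen-core", "all-electron"):
            raise ValueError(f"unknown core treatment {self.core_treatment!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.species_id, self.level, self.core_treatment)


@dataclasses.dataclass(frozen=True)
class CompositeEnergyBreakdown:
    """The three-term decomposition of one species' composite energy."""

    species_id: str
    E_base: EnergyQuantity
    delta_cbs: EnergyQuantity
    delta_cv: EnergyQuantity
    total: EnergyQuantity
    extrapolation_mode: str = "total"  # "total" | "correlation-only"

    def __post_init__(self):
        units = {self.E_base.unit, self.delta_cbs.unit, self.delta_cv.unit, self.total.unit}
        if len(units) != 1:
            raise ValueError(f"breakdown mixes units: {sorted(units)}")
        expect = self.E_base.value + self.delta_cbs.value + self.delta_cv.value
        if abs(self.total.value - expect) > 1e-9 * max(1.0, abs(expect)):
            raise ValueError(
                f"total {self.total.value} != base+dCBS+dCV = {expect} for {self.species_id}"
            )


def _same_unit(*quantities: EnergyQuantity) -> str:
    units = {q.unit for q in quantities}
    if len(units) != 1:
        raise ValueError(f"energies must share one unit, got {sorted(units)}")
    return units.pop()


def cbs_two_point(E_n: EnergyQuantity, E_m: EnergyQuantity, n: int, m: int) -> EnergyQuantity:
    """Two-point inverse-cube extrapolation to the complete-basis-set limit.

    Fits E(k) = E_CBS + A k^-3 through the two points and returns E_CBS::

        E_CBS = (m^3 E_m - n^3 E_n) / (m^3 - n^3)

    Exact (to machine precision) on any series of that form.
    """
    if n == m:
        raise ValueError(f"basis cardinals must differ, got n = m = {n}")
    unit = _same_unit(E_n, E_m)
    n3, m3 = float(n) ** 3, float(m) ** 3
    return EnergyQuantity((m3 * E_m.value - n3 * E_n.value) / (m3 - n3), unit)


def cbs_correction(
    E_mp2_T: EnergyQuantity, E_mp2_Q: EnergyQuantity, E_mp2_base: EnergyQuantity
) -> EnergyQuantity:
    """CBS correction: extrapolated MP2 limit minus MP2 at the base basis."""
    unit = _same_unit(E_mp2_T, E_mp2_Q, E_mp2_base)
    limit = cbs_two_point(E_mp2_T, E_mp2_Q, 3, 4)
    return EnergyQuantity(limit.value - E_mp2_base.value, unit)


def cv_correction(E_ae: LevelEnergyRecord, E_fc: LevelEnergyRecord) -> EnergyQuantity:
    """Core-valence correction: all-electron minus frozen-core energy.

    Both records must be the same species at the same level tag; the pair
    (all-electron, frozen-core) is enforced so arguments cannot be swapped
    silently.
    """
    if E_ae.level != E_fc.level or E_ae.species_id != E_fc.species_id:
        raise ValueError(
            f"core-valence pair mismatch: {E_ae.species_id}/{E_ae.level} vs "
            f"{E_fc.species_id}/{E_fc.level}"
        )
    if E_ae.core_treatment != "all-electron" or E_fc.core_treatment != "frozen-core":
        raise ValueError("cv_correction expects (all-electron, frozen-core) records")
    unit = _same_unit(E_ae.energy, E_fc.energy)
    return EnergyQuantity(E_ae.energy.value - E_fc.energy.value, unit)


def pcs_total(
    base: EnergyQuantity,
    delta_cbs: EnergyQuantity,
    delta_cv: EnergyQuantity,
    species_id: str = "",
    extrapolation_mode: str = "total",
) -> CompositeEnergyBreakdown:
    """Assemble the composite total and keep the three-term breakdown."""
    unit = _same_unit(base, delta_cbs, delta_cv)
    total = EnergyQuantity(base.value + delta_cbs.value + delta_cv.value, unit)
    return CompositeEnergyBreakdown(
        species_id, base, delta_cbs, delta_cv, total, extrapolation_mode
    )


def relative_energies(
    breakdowns,
    reference: str,
    registry: ConstantsRegistry | None = None,
) -> dict[str, float]:
    """Totals relative to *reference*, in cm^-1.

    The reference maps to exactly 0; the map is invariant under a uniform
    shift of all totals and antisymmetric under swapping the reference with
    any other species.
    """
    registry = registry or get_registry()
    totals = {b.species_id: b.total.in_cm(registry) for b in breakdowns}
    if reference not in totals:
        raise KeyError(f"reference species {reference!r} not among {sorted(totals)}")
    ref = totals[reference]
    return {s: (0.0 if s == reference else t - ref) for s, t in totals.items()}
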