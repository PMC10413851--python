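"""RRHO thermochemistry, Boltzmann tautomer populations, and tautomer
counting.

Everything is evaluated in cm^-1 (the spectroscopist's energy unit) with the
Boltzmann constant k_B = 0.6950348 cm^-1/K frozen in the constants registry.
The rigid-rotor harmonic-oscillator (RRHO) model is used as-is, including
for low-frequency large-amplitude modes: for amino-group inversion the
harmonic frequency is high enough (250-350 cm^-1) that the harmonic
contribution to thermodynamic functions is adequate, and no free-rotor
interpolation is applied.

Populations of tautomers/rotamers are reported both as Boltzmann ratios
against a reference species (the experimental convention when band
intensities are normalized to the most abundant form) and as mole
fractions.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .rotational import RotationalConstantSet
from .units import ConstantsRegistry, get_registry

__all__ = [
    "SpeciesThermo",
    "ThermoComponents",
    "PopulationReport",
    "zpe",
    "rrho_thermo",
    "boltzmann_populations",
    "group_mole_fraction",
    "tautomer_count",
]


@dataclasses.dataclass(frozen=True)
class SpeciesThermo:
    """Inputs for RRHO partition functions of one species."""

    species_id: str
    frequencies: tuple[float, ...]          # harmonic wavenumbers, cm^-1
    rotational: RotationalConstantSet       # MHz
    mass: float                             # amu
    symmetry_number: int = 1
    electronic_degeneracy: int = 1

    def __post_init__(self):
        bad = [f for f in self.frequencies if f <= 0]
        if bad:
            raise ValueError(
                f"{self.species_id}: non-positive harmonic frequencies {bad}; "
                "imaginary/negative modes cannot enter RRHO thermodynamics"
            )
        if self.mass <= 0:
            raise ValueError("molecular mass must be positive")
        if self.symmetry_number < 1 or self.electronic_degeneracy < 1:
            raise ValueError("symmetry number and degeneracy must be >= 1")


@dataclasses.dataclass(frozen=True)
class ThermoComponents:
    """RRHO contributions at temperature T, all in cm^-1 per molecule.

    H collects ZPE + thermal internal energy + pV; G = H - T*S.  The
    electronic energy is *not* included: add the species' relative
    electronic energy to ``G`` to rank tautomers.
    """

    temperature: float
    ZPE: float
    U_vib: float       # vibrational thermal energy above ZPE
    U_rot: float
    H_trans: float     # (5/2) k T: translational energy + pV
    S_vib: float       # entropies in cm^-1 / K
    S_rot: float
    S_trans: float
    S_elec: float

    @property
    def H(self) -> float:
        return self.ZPE + self.U_vib + self.U_rot + self.H_trans

    @property
    def S(self) -> float:
        return self.S_vib + self.S_rot + self.S_trans + self.S_elec

    @property
    def G(self) -> float:
        return self.H - self.temperature * self.S


def zpe(freqs) -> float:
    """Harmonic zero-point energy, half the sum of the wavenumbers (cm^-1)."""
    freqs = list(freqs)
    bad = [f for f in freqs if f <= 0]
    if bad:
        raise ValueError(f"non-positive frequencies in ZPE: {bad}")
    return 0.5 * math.fsum(freqs)


def rrho_thermo(
    s: SpeciesThermo,
    T: float,
    registry: ConstantsRegistry | None = None,
) -> ThermoComponents:
    """RRHO thermodynamic components of one species at temperature T (K).

    Vibrations: independent harmonic oscillators measured from the ZPE.
    Rotation: classical asymmetric-top partition function with the species'
    symmetry number.  Translation: ideal gas at the registry's standard
    pressure (1 bar).  All outputs in cm^-1 (entropies in cm^-1/K).
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    registry = registry or get_registry()
    k = registry.k_B_cm
    kT = k * T

    # vibrational
    w = np.asarray(s.frequencies, dtype=float)
    x = w / kT
    with np.errstate(over="ignore"):  # exp overflow at low T means exactly 0
        expm = np.expm1(x)
        U_vib = float(np.sum(w / expm))
        S_vib = float(k * np.sum(x / expm - np.log1p(-np.exp(-x))))

    # rotational (non-linear top); constants MHz -> cm^-1
    B_cm = s.rotational.as_array * 1e6 / (registry.c_m_s * 100.0)
    q_rot = math.sqrt(math.pi) / s.symmetry_number * math.sqrt(kT**3 / np.prod(B_cm))
    U_rot = 1.5 * kT
    S_rot = k * (math.log(q_rot) + 1.5)

    # translational (Sackur-Tetrode at standard pressure)
    m_kg = s.mass * registry.amu_kg
    kT_J = registry.k_B_J_K * T
    q_trans = (2.0 * math.pi * m_kg * kT_J / registry.h_J_s**2) ** 1.5 * (
        kT_J / registry.standard_pressure_Pa
    )
    H_trans = 2.5 * kT
    S_trans = k * (math.log(q_trans) + 2.5)

    S_elec = k * math.log(s.electronic_degeneracy)

    return ThermoComponents(
        temperature=T,
        ZPE=zpe(s.frequencies),
        U_vib=U_vib,
        U_rot=U_rot,
        H_trans=H_trans,
        S_vib=S_vib,
        S_rot=S_rot,
        S_trans=S_trans,
        S_elec=S_elec,
    )


@dataclasses.dataclass(frozen=True)
class PopulationReport:
    """Boltzmann ratios and mole fractions at one temperature."""

    temperature: float
    basis: str                            # "electronic" | "free_energy"
    reference: str
    relative_energies: dict[str, float]   # cm^-1 vs reference
    ratios: dict[str, float]              # ratio vs reference (reference -> 1)
    mole_fractions: dict[str, float]

    def __post_init__(self):
        if abs(self.ratios[self.reference] - 1.0) > 1e-12:
            raise ValueError("reference ratio must be 1")
        if any(r <= 0 for r in self.ratios.values()):
            raise ValueError("population ratios must be positive")
        if abs(sum(self.mole_fractions.values()) - 1.0) > 1e-10:
            raise ValueError("mole fractions must sum to 1")


def boltzmann_populations(
    rel_energies: dict[str, float],
    T: float,
    reference: str,
    basis: str = "electronic",
    registry: ConstantsRegistry | None = None,
) -> PopulationReport:
    """Populations from relative energies (cm^-1) at temperature T (K).

    ratio_s = exp(-(E_s - E_ref) / (k_B T)); mole fractions are the
    normalized ratios and are independent of the reference choice.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if reference not in rel_energies:
        raise KeyError(f"reference {reference!r} not among {sorted(rel_energies)}")
    registry = registry or get_registry()
    kT = registry.k_B_cm * T
    e_ref = rel_energies[reference]
    ratios = {s: math.exp(-(e - e_ref) / kT) for s, e in rel_energies.items()}
    ratios[reference] = 1.0
    z = sum(ratios.values())
    fractions = {s: r / z for s, r in ratios.items()}
    return PopulationReport(
        temperature=T,
        basis=basis,
        reference=reference,
        relative_energies={s: e - e_ref for s, e in rel_energies.items()},
        ratios=ratios,
        mole_fractions=fractions,
    )


def group_mole_fraction(report: PopulationReport, members) -> float:
    """Combined mole fraction of a set of species (e.g. both enol rotamers)."""
    members = set(members)
    unknown = members - set(report.mole_fractions)
    if unknown:
        raise KeyError(f"unknown species in group: {sorted(unknown)}")
    return sum(report.mole_fractions[s] for s in members)


def tautomer_count(A: int, B: int) -> int:
    """Number of tautomers: ways to place B labile protons on A sites.

    N_T = A! / (B! (A-B)!).  For cytosine, A = 4 tautomeric sites and
    B = 2 labile protons give N_T = 6.
    """
    if A < 0 or B < 0 or B > A:
        raise ValueError(f"need 0 <= B <= A, got A={A}, B={B}")
    return math.comb(A, B)
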