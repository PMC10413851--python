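"""Rotational constants: rigid-rotor mechanics and spectroscopic bookkeeping.

Equilibrium constants come from the principal moments of inertia of a
geometry; ground-state and semi-experimental constants are related to them
through computed vibrational corrections::

    B0_i   = Beq_i - dBvib_i          (computed ground state)
    Bse_i  = B0_i(exp) + dBvib_i      (semi-experimental equilibrium)

The sign convention dBvib = Beq - B0 is the package convention; it is the
one under which published equilibrium/ground-state/correction triples close
on each other (e.g. 3904.3 - 29.1 = 3875.2 MHz), and it makes the two
relations above exact inverses.

Error statistics (MUE, MAX and their % forms over the three constants) are
the standard figures of merit for comparing computed equilibrium constants
with semi-experimental references.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import Geometry
from .units import ConstantsRegistry, get_registry

__all__ = [
    "RotationalConstantSet",
    "ErrorStats",
    "principal_moments",
    "rotational_constants",
    "apply_vibrational_correction",
    "semi_experimental",
    "error_statistics",
    "inertial_defect",
]

_ROLES = ("equilibrium", "ground_state", "semi_experimental", "vibrational_correction")
_COLLINEAR_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class RotationalConstantSet:
    """(B_a, B_b, B_c) in MHz with a role tag and provenance."""

    species_id: str
    role: str
    B_a: float
    B_b: float
    B_c: float
    provenance: str = ""

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {_ROLES}")
        if self.role != "vibrational_correction":
            if not (self.B_a >= self.B_b >= self.B_c > 0):
                raise ValueError(
                    f"{self.species_id}/{self.role}: constants must satisfy "
                    f"B_a >= B_b >= B_c > 0, got ({self.B_a}, {self.B_b}, {self.B_c})"
                )

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.B_a, self.B_b, self.B_c])


@dataclasses.dataclass(frozen=True)
class ErrorStats:
    """Mean/max unsigned errors over the three rotational constants."""

    MUE: float       # MHz
    MAX: float       # MHz
    MUE_pct: float   # percent of the reference constant
    MAX_pct: float

    def __post_init__(self):
        if not (0.0 <= self.MUE <= self.MAX and 0.0 <= self.MUE_pct <= self.MAX_pct):
            raise ValueError("error statistics must satisfy 0 <= MUE <= MAX")


def principal_moments(g: Geometry, linear: bool = False) -> np.ndarray:
    """Principal moments of inertia I_a <= I_b <= I_c in amu Angstrom^2.

    The geometry is shifted to its center of mass; the inertia tensor is
    diagonalized with a deterministic eigenvector orientation (largest-
    magnitude component of each axis made positive) so degenerate tops give
    reproducible frames.
    """
    m = g.masses
    xyz = g.coords - (m[:, None] * g.coords).sum(axis=0) / m.sum()
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    tensor = np.array(
        [
            [(m * (y**2 + z**2)).sum(), -(m * x * y).sum(), -(m * x * z).sum()],
            [-(m * x * y).sum(), (m * (x**2 + z**2)).sum(), -(m * y * z).sum()],
            [-(m * x * z).sum(), -(m * y * z).sum(), (m * (x**2 + y**2)).sum()],
        ]
    )
    moments, vecs = np.linalg.eigh(tensor)
    # deterministic orientation for reproducibility on symmetric tops
    for j in range(3):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    moments = np.clip(moments, 0.0, None)
    scale = max(moments.max(), 1.0)
    if moments[0] < _COLLINEAR_TOL * scale and not linear:
        raise ValueError(
            f"geometry {g.species_id!r} is collinear; pass linear=True for a linear rotor"
        )
    return moments


def rotational_constants(
    g: Geometry,
    registry: ConstantsRegistry | None = None,
    provenance: str = "",
    linear: bool = False,
) -> RotationalConstantSet:
    """Equilibrium rotational constants (MHz) of a rigid rotor.

    B_i = h / (8 pi^2 I_i), with the conversion constant frozen in the
    registry.  A linear rotor (``linear=True``) has I_a = 0: the diverging
    constant about the molecular axis is reported as ``B_a = inf`` (absent
    from the spectrum) and the two finite constants are equal.
    """
    registry = registry or get_registry()
    moments = principal_moments(g, linear=linear)
    if linear:
        b = float(registry.rot_MHz_amu_A2 / moments[1])
        return RotationalConstantSet(
            g.species_id, "equilibrium", float("inf"), b, b, provenance
        )
    constants = registry.rot_MHz_amu_A2 / moments  # descending since moments ascend
    return RotationalConstantSet(
        g.species_id, "equilibrium", *constants, provenance=provenance
    )


def _check_pair(x: RotationalConstantSet, y: RotationalConstantSet, roles: tuple[str, str]):
    if x.species_id != y.species_id:
        raise ValueError(f"species mismatch: {x.species_id!r} vs {y.species_id!r}")
    if (x.role, y.role) != roles:
        raise ValueError(f"expected roles {roles}, got ({x.role!r}, {y.role!r})")


def apply_vibrational_correction(
    B_eq: RotationalConstantSet, dB_vib: RotationalConstantSet
) -> RotationalConstantSet:
    """Ground-state constants B0 = Beq - dBvib, per inertial axis."""
    _check_pair(B_eq, dB_vib, ("equilibrium", "vibrational_correction"))
    b = B_eq.as_array - dB_vib.as_array
    return RotationalConstantSet(
        B_eq.species_id, "ground_state", *b,
        provenance=f"{B_eq.provenance}-{dB_vib.provenance}vib" if B_eq.provenance else "computed",
    )


def semi_experimental(
    B0_exp: RotationalConstantSet, dB_vib: RotationalConstantSet
) -> RotationalConstantSet:
    """Semi-experimental equilibrium constants Bse = B0(exp) + dBvib."""
    _check_pair(B0_exp, dB_vib, ("ground_state", "vibrational_correction"))
    b = B0_exp.as_array + dB_vib.as_array
    return RotationalConstantSet(
        B0_exp.species_id, "semi_experimental", *b,
        provenance=f"exp+{dB_vib.provenance}vib" if dB_vib.provenance else "semi-experimental",
    )


def error_statistics(
    computed: RotationalConstantSet, reference: RotationalConstantSet
) -> ErrorStats:
    """MUE/MAX (MHz) and MUE%/MAX% of *computed* against *reference*."""
    if computed.species_id != reference.species_id:
        raise ValueError(
            f"species mismatch: {computed.species_id!r} vs {reference.species_id!r}"
        )
    ref = reference.as_array
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(computed.as_array))):
        raise ValueError("error statistics need three finite constants per set")
    if np.any(ref <= 0):
        raise ValueError("reference constants must be positive")
    dev = np.abs(computed.as_array - ref)
    pct = 100.0 * dev / ref
    return ErrorStats(float(dev.mean()), float(dev.max()), float(pct.mean()), float(pct.max()))


def inertial_defect(B: RotationalConstantSet, registry: ConstantsRegistry | None = None) -> float:
    """Inertial defect Delta = I_c - I_a - I_b in amu Angstrom^2.

    Zero for a rigid planar molecule; small negative values diagnose
    out-of-plane mass (e.g. slightly pyramidalized amino groups).
    """
    registry = registry or get_registry()
    moments = registry.rot_MHz_amu_A2 / B.as_array  # I_a, I_b, I_c
    return float(moments[2] - moments[0] - moments[1])
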