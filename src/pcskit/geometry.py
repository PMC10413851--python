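"""Molecular geometry container shared by the rotational and internal
coordinate machinery.

Atom ordering is significant (internal-coordinate specs and the additive
geometry combination index into it) and preserved by every transformation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .masses import MassTable, default_mass_table

__all__ = ["Atom", "Geometry"]


@dataclasses.dataclass(frozen=True)
class Atom:
    element: str
    mass: float        # amu; explicit so isotopologues are first-class
    xyz: tuple[float, float, float]  # Angstrom


@dataclasses.dataclass
class Geometry:
    """Ordered collection of mass points in Cartesian space (Angstrom)."""

    species_id: str
    atoms: list[Atom]

    def __post_init__(self):
        if len(self.atoms) < 2:
            raise ValueError(
                f"geometry {self.species_id!r} needs at least 2 atoms, got {len(self.atoms)}"
            )
        for i, a in enumerate(self.atoms):
            if a.mass <= 0:
                raise ValueError(f"atom {i} ({a.element}) has non-positive mass {a.mass}")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        species_id: str,
        elements,
        coords,
        masses=None,
        isotopes=None,
        mass_table: MassTable | None = None,
    ) -> "Geometry":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if masses is None:
            table = mass_table or default_mass_table()
            isotopes = isotopes or [None] * len(elements)
            masses = [table.lookup(e, iso) for e, iso in zip(elements, isotopes)]
        atoms = [
            Atom(e, float(m), (float(x), float(y), float(z)))
            for e, m, (x, y, z) in zip(elements, masses, coords, strict=True)
        ]
        return cls(species_id, atoms)

    # -- array views ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    # -- transforms ----------------------------------------------------
    def transformed(self, rotation=None, translation=None, species_id=None) -> "Geometry":
        """Rigid-motion copy (atom order preserved)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return Geometry.from_arrays(
            species_id or self.species_id, self.elements, xyz, masses=self.masses
        )

    def with_coords(self, coords, species_id=None) -> "Geometry":
        return Geometry.from_arrays(
            species_id or self.species_id, self.elements, coords, masses=self.masses
        )
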