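"""Interchange formats: XYZ geometries, CSV tables, JSON reports.

XYZ files are the plain Cartesian convention: an atom-count line, a comment
line, then ``element x y z`` per atom in Angstrom.  Parse errors carry line
numbers.  Masses are attached from the bundled table (principal isotopes)
at read time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .composite import CompositeEnergyBreakdown, LevelEnergyRecord
from .geometry import Geometry
from .masses import MassTable, default_mass_table
from .rotational import RotationalConstantSet
from .thermo import PopulationReport
from .units import EnergyQuantity

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_level_energies",
    "read_rotational_csv",
    "write_rotational_csv",
    "breakdown_to_dict",
    "population_report_to_dict",
]


def read_xyz(
    path,
    species_id: str | None = None,
    mass_table: MassTable | None = None,
) -> Geometry:
    """Read one geometry from an XYZ file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}:1: expected an atom count, got {lines[0]!r}") from None
    if len(lines) < n + 2:
        raise ValueError(
            f"{path}: count line promises {n} atoms but file has only "
            f"{max(0, len(lines) - 2)} atom lines"
        )
    elements, coords = [], []
    for i in range(n):
        lineno = i + 3
        fields = lines[i + 2].split()
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected 'element x y z', got {lines[i + 2]!r}")
        try:
            xyz = [float(v) for v in fields[1:4]]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate in {fields[1:4]}") from None
        elements.append(fields[0])
        coords.append(xyz)
    # extra non-blank lines after the promised atoms indicate a bad count
    for j, extra in enumerate(lines[n + 2 :], start=n + 3):
        if extra.strip():
            raise ValueError(f"{path}:{j}: unexpected content past the declared {n} atoms")
    return Geometry.from_arrays(
        species_id or path.stem, elements, coords, mass_table=mass_table
    )


def write_xyz(g: Geometry, path, comment: str = "") -> None:
    path = Path(path)
    lines = [str(g.n_atoms), comment or g.species_id]
    for a in g.atoms:
        x, y, z = a.xyz
        lines.append(f"{a.element:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(lines) + "\n")


def read_level_energies(path) -> list[LevelEnergyRecord]:
    """Level-energy CSV: species_id, level, core_treatment, energy, unit."""
    df = pd.read_csv(path)
    required = {"species_id", "level", "core_treatment", "energy", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    seen = set()
    for _, r in df.iterrows():
        rec = LevelEnergyRecord(
            species_id=str(r["species_id"]),
            level=str(r["level"]),
            core_treatment=str(r["core_treatment"]),
            energy=EnergyQuantity(float(r["energy"]), str(r["unit"])),
        )
        if rec.key in seen:
            raise ValueError(f"{path}: duplicate record {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def read_rotational_csv(path) -> list[RotationalConstantSet]:
    """Constants CSV: species_id, role, provenance, B_a, B_b, B_c (MHz)."""
    df = pd.read_csv(path)
    return [
        RotationalConstantSet(
            str(r["species_id"]), str(r["role"]),
            float(r["B_a"]), float(r["B_b"]), float(r["B_c"]),
            str(r.get("provenance", "")),
        )
        for _, r in df.iterrows()
    ]


def write_rotational_csv(sets, path) -> None:
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "role": s.role,
                "provenance": s.provenance,
                "B_a": s.B_a,
                "B_b": s.B_b,
                "B_c": s.B_c,
            }
            for s in sets
        ]
    ).to_csv(path, index=False)


def breakdown_to_dict(b: CompositeEnergyBreakdown) -> dict:
    return {
        "species_id": b.species_id,
        "E_base": dataclasses.asdict(b.E_base),
        "delta_cbs": dataclasses.asdict(b.delta_cbs),
        "delta_cv": dataclasses.asdict(b.delta_cv),
        "total": dataclasses.asdict(b.total),
        "extrapolation_mode": b.extrapolation_mode,
    }


def population_report_to_dict(report: PopulationReport) -> dict:
    return {
        "temperature_K": report.temperature,
        "basis": report.basis,
        "reference": report.reference,
        "relative_energies_cm": report.relative_energies,
        "ratios": report.ratios,
        "mole_fractions": report.mole_fractions,
    }


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
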