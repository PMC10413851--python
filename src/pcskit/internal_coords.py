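"""Internal coordinates and the additive "geometry scheme".

The composite geometry is assembled per geometrical parameter rather than per
Cartesian coordinate (Cartesian additivity is frame-dependent)::

    r_composite = r_base + (r_all_electron - r_frozen_core)

for every bond, angle and dihedral of a caller-supplied, Z-matrix-ordered
internal-coordinate spec.  Dihedral arithmetic is done on the circle
(shortest signed arc), so the combination behaves sensibly near +-180 deg.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .geometry import Geometry

__all__ = [
    "Parameter",
    "InternalCoordinateSpec",
    "ParameterVector",
    "extract_internals",
    "geometry_scheme",
    "rebuild_cartesian",
    "wrap_degrees",
]

_KINDS = ("bond", "angle", "dihedral")
_LIN_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class Parameter:
    kind: str                 # bond | angle | dihedral
    indices: tuple[int, ...]  # 2, 3 or 4 atom indices; units Angstrom / degrees

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        need = {"bond": 2, "angle": 3, "dihedral": 4}[self.kind]
        if len(self.indices) != need:
            raise ValueError(f"{self.kind} needs {need} indices, got {self.indices}")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError(f"repeated atom index in {self.kind} {self.indices}")

    def __str__(self) -> str:
        return f"{self.kind}{self.indices}"


@dataclasses.dataclass(frozen=True)
class InternalCoordinateSpec:
    """Ordered list of internal-coordinate parameters over one atom ordering.

    For reconstruction the spec must be Z-matrix shaped: with atom 0 at the
    origin, the parameters place atom 1 by one bond, atom 2 by bond + angle,
    and every later atom k by bond + angle + dihedral whose reference atoms
    all have indices < k.  Extraction works for any valid spec.
    """

    parameters: tuple[Parameter, ...]
    n_atoms: int
    linear: bool = False

    def __post_init__(self):
        if self.n_atoms < 2:
            raise ValueError("spec needs at least 2 atoms")
        for p in self.parameters:
            if max(p.indices) >= self.n_atoms or min(p.indices) < 0:
                raise ValueError(f"parameter {p} indexes outside 0..{self.n_atoms - 1}")
        expected = 1 if self.n_atoms == 2 else 3 * self.n_atoms - (5 if self.linear else 6)
        if len(self.parameters) != expected:
            raise ValueError(
                f"spec has {len(self.parameters)} parameters; a complete set for "
                f"{self.n_atoms} atoms ({'linear' if self.linear else 'non-linear'}) "
                f"has {expected}"
            )

    @classmethod
    def zmatrix(cls, entries, linear: bool = False) -> "InternalCoordinateSpec":
        """Build a Z-matrix-ordered spec.

        *entries* is a sequence over atoms 1..N-1: ``(bond_ref,)`` for atom 1,
        ``(bond_ref, angle_ref)`` for atom 2, ``(bond_ref, angle_ref,
        dihedral_ref)`` afterwards.
        """
        entries = list(entries)
        params: list[Parameter] = []
        for k, refs in enumerate(entries, start=1):
            if k == 1:
                (b,) = refs
                params.append(Parameter("bond", (1, b)))
            elif k == 2:
                b, a = refs
                params.append(Parameter("bond", (2, b)))
                params.append(Parameter("angle", (2, b, a)))
            else:
                b, a, d = refs
                params.append(Parameter("bond", (k, b)))
                params.append(Parameter("angle", (k, b, a)))
                params.append(Parameter("dihedral", (k, b, a, d)))
            if max(refs) >= k:
                raise ValueError(f"atom {k} references a not-yet-placed atom {max(refs)}")
        return cls(tuple(params), n_atoms=len(entries) + 1, linear=linear)

    def zmatrix_rows(self):
        """Group parameters per placed atom; error if not Z-matrix shaped."""
        by_atom: dict[int, dict[str, Parameter]] = {}
        for p in self.parameters:
            atom = p.indices[0]
            if any(i >= atom for i in p.indices[1:]):
                raise ValueError(
                    f"parameter {p} is not Z-matrix ordered (reference >= placed atom)"
                )
            by_atom.setdefault(atom, {})[p.kind] = p
        rows = []
        for k in range(1, self.n_atoms):
            row = by_atom.get(k, {})
            need = ["bond"] if k == 1 else ["bond", "angle"] if k == 2 else _KINDS
            if sorted(row) != sorted(need):
                raise ValueError(f"atom {k} placement needs {need}, has {sorted(row)}")
            rows.append(row)
        return rows


@dataclasses.dataclass
class ParameterVector:
    """Values (Angstrom / degrees) aligned with an InternalCoordinateSpec."""

    spec: InternalCoordinateSpec
    values: np.ndarray
    level: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.spec.parameters),):
            raise ValueError(
                f"expected {len(self.spec.parameters)} values, got {self.values.shape}"
            )
        for p, v in zip(self.spec.parameters, self.values):
            if p.kind == "bond" and v <= 0:
                raise ValueError(f"non-positive bond length {v} for {p}")
            if p.kind == "angle" and not (0.0 < v < 180.0):
                raise ValueError(f"angle {v} for {p} outside (0, 180)")
        # dihedrals normalized to (-180, 180]
        for i, p in enumerate(self.spec.parameters):
            if p.kind == "dihedral":
                self.values[i] = wrap_degrees(self.values[i])


def wrap_degrees(x: float) -> float:
    """Wrap an angle to (-180, 180]."""
    w = math.fmod(x, 360.0)
    if w <= -180.0:
        w += 360.0
    elif w > 180.0:
        w -= 360.0
    return w


# ---------------------------------------------------------------------------
# extraction

def _bond(xyz, i, j) -> float:
    return float(np.linalg.norm(xyz[i] - xyz[j]))


def _angle(xyz, i, j, k, what="") -> float:
    u, v = xyz[i] - xyz[j], xyz[k] - xyz[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _LIN_TOL or nv < _LIN_TOL:
        raise ValueError(f"coincident atoms in angle {what or (i, j, k)}")
    cosang = float(np.dot(u, v) / (nu * nv))
    cosang = max(-1.0, min(1.0, cosang))
    if 1.0 - abs(cosang) < _LIN_TOL:
        raise ValueError(f"collinear atoms in angle {what or (i, j, k)}")
    return math.degrees(math.acos(cosang))


def _dihedral(xyz, i, j, k, l, what="") -> float:
    b1, b2, b3 = xyz[j] - xyz[i], xyz[k] - xyz[j], xyz[l] - xyz[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < _LIN_TOL or np.linalg.norm(n2) < _LIN_TOL:
        raise ValueError(f"collinear atoms in dihedral {what or (i, j, k, l)}")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    return wrap_degrees(math.degrees(math.atan2(y, x)))


def extract_internals(g: Geometry, spec: InternalCoordinateSpec, level: str = "") -> ParameterVector:
    """Evaluate the spec's bonds/angles/dihedrals from Cartesians."""
    if g.n_atoms != spec.n_atoms:
        raise ValueError(f"geometry has {g.n_atoms} atoms, spec expects {spec.n_atoms}")
    xyz = g.coords
    vals = []
    for p in spec.parameters:
        if p.kind == "bond":
            vals.append(_bond(xyz, *p.indices))
        elif p.kind == "angle":
            vals.append(_angle(xyz, *p.indices, what=str(p)))
        else:
            vals.append(_dihedral(xyz, *p.indices, what=str(p)))
    return ParameterVector(spec, np.array(vals), level=level)


# ---------------------------------------------------------------------------
# combination

def geometry_scheme(
    r_base: ParameterVector, r_ae: ParameterVector, r_fc: ParameterVector
) -> ParameterVector:
    """Per-parameter additive combination r_base + (r_ae - r_fc).

    All three vectors must share the same spec object (or an equal one);
    dihedral shifts are taken as the shortest signed arc.
    """
    if not (r_base.spec == r_ae.spec == r_fc.spec):
        raise ValueError("parameter vectors are aligned to different specs")
    out = np.empty_like(r_base.values)
    for i, p in enumerate(r_base.spec.parameters):
        if p.kind == "dihedral":
            shift = wrap_degrees(r_ae.values[i] - r_fc.values[i])
            out[i] = wrap_degrees(r_base.values[i] + shift)
        else:
            out[i] = r_base.values[i] + (r_ae.values[i] - r_fc.values[i])
    return ParameterVector(r_base.spec, out, level=f"{r_base.level}+CV" if r_base.level else "composite")


# ---------------------------------------------------------------------------
# reconstruction (natural-extension reference frame placement)

def rebuild_cartesian(
    spec: InternalCoordinateSpec,
    r: ParameterVector,
    elements=None,
    masses=None,
    species_id: str = "rebuilt",
) -> Geometry:
    """Place atoms sequentially from a Z-matrix-shaped spec.

    Atom 0 sits at the origin, atom 1 on +x, atom 2 in the xy-plane; each
    later atom is placed in the local frame of its three reference atoms.
    A reference frame degenerate to a line (angle at 0/180 deg) is an error.
    """
    if r.spec != spec:
        raise ValueError("parameter vector is not aligned to this spec")
    rows = spec.zmatrix_rows()
    value_of = dict(zip(spec.parameters, r.values))
    n = spec.n_atoms
    xyz = np.zeros((n, 3))
    for k, row in enumerate(rows, start=1):
        dist = value_of[row["bond"]]
        b = row["bond"].indices[1]
        if k == 1:
            xyz[1] = xyz[b] + np.array([dist, 0.0, 0.0])
            continue
        ang = math.radians(value_of[row["angle"]])
        a = row["angle"].indices[2]
        if k == 2:
            # place in xy-plane relative to bond ref b and angle ref a
            u = xyz[a] - xyz[b]
            nu = np.linalg.norm(u)
            if nu < _LIN_TOL:
                raise ValueError("angle reference coincides with bond reference")
            u /= nu
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < _LIN_TOL:  # u along z (cannot happen here)
                perp = np.array([1.0, 0.0, 0.0])
            perp /= np.linalg.norm(perp)
            xyz[2] = xyz[b] + dist * (math.cos(ang) * u + math.sin(ang) * perp)
            continue
        if math.sin(ang) < _LIN_TOL:
            raise ValueError(
                f"cannot place atom {k}: angle {math.degrees(ang):.6g} deg is degenerate"
            )
        tor = math.radians(value_of[row["dihedral"]])
        d = row["dihedral"].indices[3]
        bc = xyz[b] - xyz[a]
        nbc = np.linalg.norm(bc)
        ab = xyz[a] - xyz[d]
        if nbc < _LIN_TOL:
            raise ValueError(f"cannot place atom {k}: coincident reference atoms")
        bc /= nbc
        n1 = np.cross(ab, bc)
        if np.linalg.norm(n1) < _LIN_TOL:
            raise ValueError(
                f"cannot place atom {k}: reference atoms {d},{a},{b} are collinear"
            )
        n1 /= np.linalg.norm(n1)
        m1 = np.cross(n1, bc)
        local = dist * np.array(
            [
                -math.cos(ang),
                math.sin(ang) * math.cos(tor),
                math.sin(ang) * math.sin(tor),
            ]
        )
        xyz[k] = xyz[b] + local[0] * bc + local[1] * m1 + local[2] * n1
    if elements is None:
        elements = ["X"] * n
    if masses is None:
        masses = [1.0] * n
    return Geometry.from_arrays(species_id, elements, xyz, masses=masses)
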