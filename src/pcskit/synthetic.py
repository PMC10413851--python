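"""Seeded synthetic inputs for exercising the analysis pipeline.

Three generator kinds:

* ``rigid_rotor`` — a point-mass geometry with prescribed principal moments
  of inertia, built by closed form (masses on the principal axes) and then
  rigidly rotated/translated, so the inertia pipeline can be tested against
  exact targets in a general frame;
* ``cbs_series`` — energies following the exact basis-set convergence law
  E(k) = E_CBS + A k^-p, the family on which two-point extrapolation is
  exact when p matches;
* ``mode_set`` — harmonic/anharmonic mode records with a prescribed shift
  distribution for the hybrid IR assembly.

Same seed + spec always reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import Geometry

__all__ = [
    "SyntheticSpec",
    "synthetic_rigid_rotor",
    "synthetic_cbs_series",
    "synthetic_mode_set",
]

_KINDS = ("rigid_rotor", "cbs_series", "mode_set")


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    kind: str
    parameters: dict

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; one of {_KINDS}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def synthetic_rigid_rotor(spec: SyntheticSpec) -> Geometry:
    """Point-mass rotor with prescribed principal moments (amu Angstrom^2).

    Parameters: ``moments`` (I_a <= I_b <= I_c, > 0), optional ``planar``
    (demands I_c = I_a + I_b to 1e-8 and builds an exactly planar body),
    optional ``randomize_frame`` (default True).

    Construction: with axis second moments S_x = sum m x^2 etc., the
    principal moments are I_x = S_y + S_z (cyclic), so S follows from the
    targets by closed form; unit masses are placed pairwise at +-sqrt(S/2)
    on each axis.  S >= 0 requires I_c <= I_a + I_b, the triangle condition
    every rigid body satisfies; a triple violating it is infeasible.
    """
    if spec.kind != "rigid_rotor":
        raise ValueError(f"spec kind is {spec.kind!r}, expected 'rigid_rotor'")
    I = np.asarray(spec.parameters["moments"], dtype=float)
    planar = bool(spec.parameters.get("planar", False))
    if I.shape != (3,) or np.any(I <= 0):
        raise ValueError(f"need three positive moments, got {I}")
    if np.any(np.diff(I) < 0):
        raise ValueError(f"moments must be sorted I_a <= I_b <= I_c, got {I}")
    S = np.array(
        [
            (I[1] + I[2] - I[0]) / 2.0,
            (I[0] + I[2] - I[1]) / 2.0,
            (I[0] + I[1] - I[2]) / 2.0,
        ]
    )
    if S[2] < -1e-8:
        raise ValueError(
            f"infeasible moment triple {I}: no rigid body has I_c > I_a + I_b"
        )
    if planar and abs(S[2]) > 1e-8:
        raise ValueError(
            f"planar rotor requires I_c = I_a + I_b, got defect {I[2] - I[0] - I[1]:g}"
        )
    coords, masses = [], []
    for axis in range(3):
        s = max(S[axis], 0.0)
        if planar and axis == 2:
            continue
        if s == 0.0:
            continue
        x = np.sqrt(s / 2.0)
        for sign in (+1.0, -1.0):
            p = np.zeros(3)
            p[axis] = sign * x
            coords.append(p)
            masses.append(1.0)
    if len(coords) < 2:  # fully degenerate request (all moments equal zero S)
        raise ValueError(f"degenerate moment triple {I} yields no extended body")
    g = Geometry.from_arrays(
        f"synthetic-rotor-{spec.seed}", ["X"] * len(coords), np.array(coords), masses=masses
    )
    if spec.parameters.get("randomize_frame", True):
        rng = spec.rng()
        g = g.transformed(rotation=_random_rotation(rng), translation=rng.normal(scale=5.0, size=3))
    return g


def synthetic_cbs_series(spec: SyntheticSpec) -> list[tuple[int, float]]:
    """Energy series E(k) = E_CBS + A k^-p at the requested cardinals.

    Parameters: ``E_cbs``, ``A``, optional ``exponent`` (p, default 3; must
    be > 0) and ``cardinals`` (default (3, 4)).
    """
    if spec.kind != "cbs_series":
        raise ValueError(f"spec kind is {spec.kind!r}, expected 'cbs_series'")
    p = float(spec.parameters.get("exponent", 3.0))
    if p <= 0:
        raise ValueError(f"exponent must be positive, got {p}")
    e_cbs = float(spec.parameters["E_cbs"])
    a = float(spec.parameters["A"])
    cardinals = tuple(spec.parameters.get("cardinals", (3, 4)))
    return [(int(k), e_cbs + a * float(k) ** (-p)) for k in cardinals]


def synthetic_mode_set(spec: SyntheticSpec) -> list[dict]:
    """Random mode records for hybrid IR assembly.

    Parameters: ``n_modes``, optional ``shift_scale`` (cm^-1 std-dev of the
    anharmonic shift, default 30; shifts drawn negative-leaning as real
    anharmonic corrections are) and ``n_failures`` (modes given a
    non-positive anharmonic fundamental to exercise the fallback).
    """
    if spec.kind != "mode_set":
        raise ValueError(f"spec kind is {spec.kind!r}, expected 'mode_set'")
    n = int(spec.parameters["n_modes"])
    scale = float(spec.parameters.get("shift_scale", 30.0))
    n_fail = int(spec.parameters.get("n_failures", 0))
    if n < 1 or n_fail > n:
        raise ValueError(f"need 1 <= n_failures <= n_modes, got {n_fail}, {n}")
    rng = spec.rng()
    omega_high = np.sort(rng.uniform(100.0, 3800.0, size=n))[::-1]
    omega_low = omega_high * rng.uniform(0.97, 1.03, size=n)
    shift = -np.abs(rng.normal(scale=scale, size=n))
    nu_anh = omega_low + shift
    fail = rng.choice(n, size=n_fail, replace=False)
    nu_anh[fail] = -np.abs(nu_anh[fail])
    return [
        {
            "mode_index": i + 1,
            "label": f"m{i + 1}",
            "omega_high": float(omega_high[i]),
            "omega_low": float(omega_low[i]),
            "nu_low_anh": float(nu_anh[i]),
            "intensity": float(rng.uniform(0.0, 500.0)),
        }
        for i in range(n)
    ]
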