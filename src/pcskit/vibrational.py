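"""Hybrid anharmonic IR spectra.

A hybrid force-field fundamental combines a high-level harmonic frequency
with an anharmonic shift taken from a cheaper level::

    nu_hybrid = omega_high + (nu_low_anh - omega_low)

Second-order vibrational perturbation theory (VPT2) breaks down for
large-amplitude motions such as amino-group inversion: the low-level
anharmonic fundamental can come out non-positive or absurdly shifted.  For
such modes the assembly falls back to the high-level harmonic value and
flags the mode, which is the convention that reproduces published hybrid
tables for the inversion modes of cytosine's amino tautomers.
"""

from __future__ import annotations

import dataclasses

__all__ = [
    "FallbackPolicy",
    "VibrationalMode",
    "SpectrumTable",
    "hybrid_frequency",
    "build_spectrum",
    "assign_bands",
]


@dataclasses.dataclass(frozen=True)
class FallbackPolicy:
    """When to distrust the low-level anharmonic fundamental.

    Fallback fires when nu_low_anh <= 0 (VPT2 collapsed) or when the
    anharmonic shift magnitude exceeds ``max_shift`` (default 300 cm^-1, a
    value no genuine fundamental shift of a semi-rigid organic molecule
    approaches).
    """

    max_shift: float = 300.0

    def triggers(self, omega_low: float, nu_low_anh: float) -> bool:
        return nu_low_anh <= 0 or abs(nu_low_anh - omega_low) > self.max_shift


@dataclasses.dataclass(frozen=True)
class VibrationalMode:
    mode_index: int
    label: str
    omega_high: float           # high-level harmonic, cm^-1
    omega_low: float            # low-level harmonic, cm^-1
    nu_low_anh: float           # low-level anharmonic fundamental, cm^-1
    hybrid: float               # assembled hybrid fundamental, cm^-1
    intensity: float | None = None  # high-level harmonic intensity, km/mol
    fallback_applied: bool = False

    def __post_init__(self):
        if self.omega_high <= 0 or self.omega_low <= 0:
            raise ValueError(
                f"mode {self.mode_index} ({self.label}): harmonic frequencies must be "
                f"positive, got omega_high={self.omega_high}, omega_low={self.omega_low}"
            )
        if self.hybrid <= 0:
            raise ValueError(f"mode {self.mode_index}: assembled hybrid must be positive")

    @property
    def anharmonic_shift(self) -> float:
        return self.nu_low_anh - self.omega_low


@dataclasses.dataclass(frozen=True)
class SpectrumTable:
    species_id: str
    modes: tuple[VibrationalMode, ...]
    level_high: str = ""
    level_low: str = ""

    def __post_init__(self):
        indices = [m.mode_index for m in self.modes]
        if sorted(indices) != list(range(1, len(indices) + 1)):
            raise ValueError(
                f"{self.species_id}: mode indices must be unique and contiguous "
                f"from 1, got {sorted(indices)}"
            )

    def mode(self, index: int) -> VibrationalMode:
        for m in self.modes:
            if m.mode_index == index:
                return m
        raise KeyError(f"no mode {index} in {self.species_id}")

    @property
    def hybrid_frequencies(self) -> list[float]:
        return [m.hybrid for m in self.modes]


def hybrid_frequency(
    omega_high: float,
    omega_low: float,
    nu_low_anh: float,
    policy: FallbackPolicy | None = None,
) -> tuple[float, bool]:
    """Assemble one hybrid fundamental; returns (frequency, fallback flag)."""
    if omega_high <= 0 or omega_low <= 0:
        raise ValueError(
            f"harmonic frequencies must be positive, got {omega_high}, {omega_low}"
        )
    policy = policy or FallbackPolicy()
    if policy.triggers(omega_low, nu_low_anh):
        return omega_high, True
    return omega_high + (nu_low_anh - omega_low), False


def build_spectrum(
    records,
    species_id: str,
    policy: FallbackPolicy | None = None,
    level_high: str = "",
    level_low: str = "",
) -> SpectrumTable:
    """Assemble a full spectrum from per-mode records.

    Each record is a mapping with keys ``mode_index``, ``label``,
    ``omega_high``, ``omega_low``, ``nu_low_anh`` and optionally
    ``intensity``.  Input order is irrelevant; the table is sorted by mode
    index, and duplicate indices are an error.
    """
    policy = policy or FallbackPolicy()
    seen = set()
    modes = []
    for rec in records:
        idx = int(rec["mode_index"])
        if idx in seen:
            raise ValueError(f"{species_id}: duplicate mode index {idx}")
        seen.add(idx)
        hyb, flag = hybrid_frequency(
            float(rec["omega_high"]), float(rec["omega_low"]),
            float(rec["nu_low_anh"]), policy,
        )
        intensity = rec.get("intensity")
        modes.append(
            VibrationalMode(
                mode_index=idx,
                label=str(rec.get("label", "")),
                omega_high=float(rec["omega_high"]),
                omega_low=float(rec["omega_low"]),
                nu_low_anh=float(rec["nu_low_anh"]),
                hybrid=hyb,
                intensity=None if intensity is None else float(intensity),
                fallback_applied=flag,
            )
        )
    modes.sort(key=lambda m: m.mode_index)
    return SpectrumTable(species_id, tuple(modes), level_high, level_low)


def assign_bands(
    spectrum: SpectrumTable,
    observed,
    window: float,
) -> dict[int, tuple[float, float] | None]:
    """Greedy one-to-one matching of computed modes to observed bands.

    Computed modes are taken in order of decreasing intensity (unknown
    intensities last) and matched to the nearest unassigned observed band
    within ``window`` cm^-1, mirroring manual spectroscopic practice.
    Returns {mode_index: (observed frequency, residual) or None}; bands
    left unmatched simply never appear as values.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    observed = [(float(f), (None if i is None else float(i))) for f, i in observed]
    free = list(range(len(observed)))
    order = sorted(
        spectrum.modes,
        key=lambda m: (-(m.intensity if m.intensity is not None else -1.0), m.mode_index),
    )
    assignment: dict[int, tuple[float, float] | None] = {
        m.mode_index: None for m in spectrum.modes
    }
    for m in order:
        best, best_dist = None, window
        for j in free:
            dist = abs(observed[j][0] - m.hybrid)
            if dist <= best_dist:
                best, best_dist = j, dist
        if best is not None:
            free.remove(best)
            assignment[m.mode_index] = (observed[best][0], m.hybrid - observed[best][0])
    return assignment
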