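"""Isotopic atomic masses (AME2020) and the main-isotopologue convention.

Rotational spectroscopy quotes constants for the main isotopologue, so the
default mass of an element here is its principal (most abundant) isotope:
1H, 12C, 14N, 16O, ...  Per-atom isotope overrides select minor isotopes
explicitly; an unknown element or isotope is an error, never a silent
default.
"""

from __future__ import annotations

import csv
from importlib import resources

__all__ = ["MassTable", "lookup_mass"]


class MassTable:
    """Map (element, isotope) -> mass in amu, loaded from the bundled CSV."""

    def __init__(self, rows=None):
        self._by_isotope: dict[tuple[str, int], float] = {}
        self._principal: dict[str, float] = {}
        rows = rows if rows is not None else self._bundled_rows()
        for element, isotope, mass, principal in rows:
            if mass <= 0:
                raise ValueError(f"non-positive mass for {element}-{isotope}")
            self._by_isotope[(element, isotope)] = mass
            if principal:
                self._principal[element] = mass
        for required in ("H", "C", "N", "O"):
            if required not in self._principal:
                raise ValueError(f"mass table missing required element {required}")

    @staticmethod
    def _bundled_rows():
        text = resources.files("pcskit.data").joinpath("masses.csv").read_text()
        for rec in csv.DictReader(text.splitlines()):
            yield (
                rec["element"],
                int(rec["isotope"]),
                float(rec["mass_amu"]),
                rec["principal"] == "1",
            )

    def lookup(self, element: str, isotope: int | None = None) -> float:
        """Mass in amu of *element*; principal isotope unless one is given."""
        if isotope is None:
            try:
                return self._principal[element]
            except KeyError:
                raise KeyError(f"unknown element {element!r} in mass table") from None
        try:
            return self._by_isotope[(element, isotope)]
        except KeyError:
            raise KeyError(
                f"unknown isotope {isotope} of element {element!r} in mass table"
            ) from None

    def elements(self) -> set[str]:
        return set(self._principal)


_DEFAULT: MassTable | None = None


def default_mass_table() -> MassTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = MassTable()
    return _DEFAULT


def lookup_mass(element: str, isotope: int | None = None) -> float:
    """Convenience lookup against the bundled table."""
    return default_mass_table().lookup(element, isotope)
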