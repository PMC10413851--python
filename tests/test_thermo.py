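"""ZPE, RRHO limits, Boltzmann populations, tautomer combinatorics."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcskit import fixtures
from pcskit.rotational import RotationalConstantSet
from pcskit.thermo import (
    SpeciesThermo,
    boltzmann_populations,
    group_mole_fraction,
    rrho_thermo,
    tautomer_count,
    zpe,
)
from pcskit.units import round_half_away


def make_species(species_id="s", freqs=(1000.0, 500.0, 200.0), mass=111.043):
    rot = RotationalConstantSet(species_id, "equilibrium", 3900.0, 2030.0, 1335.0)
    return SpeciesThermo(species_id, tuple(freqs), rot, mass)


class TestZpe:
    def test_empty_and_hand_arithmetic(self):
        assert zpe([]) == 0.0
        assert zpe([100.0, 300.0]) == 200.0

    def test_equals_half_the_harmonic_column_sum(self):
        # spreadsheet-style oracle over the bundled 33-mode table
        df = fixtures.load_fixture("table6_modes")
        freqs = df["rdsd_h"].astype(float).tolist()
        assert zpe(freqs) == pytest.approx(0.5 * sum(freqs))

    def test_imaginary_modes_listed_in_error(self):
        with pytest.raises(ValueError, match=r"-216"):
            zpe([3715.0, -216.0])


class TestRrhoLimits:
    def test_low_temperature_free_energy_difference_tends_to_zpe_difference(self, registry):
        a = make_species("a", freqs=(1000.0, 600.0))
        b = make_species("b", freqs=(900.0, 500.0))
        dG = []
        for T in (20.0, 5.0, 1.0):
            ta, tb = rrho_thermo(a, T, registry), rrho_thermo(b, T, registry)
            # same mass and rotor: vibrations dominate the difference
            dG.append((tb.G - ta.G))
        d_zpe = zpe(b.frequencies) - zpe(a.frequencies)
        assert dG[-1] == pytest.approx(d_zpe, abs=1e-6)
        assert abs(dG[1] - d_zpe) <= abs(dG[0] - d_zpe)  # monotone approach

    def test_vibrational_thermal_energy_vanishes_at_low_T(self, registry):
        t = rrho_thermo(make_species(), 1.0, registry)
        assert t.U_vib == pytest.approx(0.0, abs=1e-12)

    def test_classical_equipartition_limit(self, registry):
        # one mode with k_B T = 100 omega: U_vib -> k_B T within 1%
        omega = 10.0
        T = 100.0 * omega / registry.k_B_cm
        t = rrho_thermo(make_species(freqs=(omega,)), T, registry)
        assert t.U_vib == pytest.approx(registry.k_B_cm * T, rel=0.01)

    def test_translational_free_energy_mass_dependence(self, registry):
        # closed form: dG_trans = -(3/2) k_B T ln(m2/m1) at fixed T
        m1, m2, T = 100.0, 150.0, 300.0
        g1 = rrho_thermo(make_species(mass=m1), T, registry)
        g2 = rrho_thermo(make_species(mass=m2), T, registry)
        expected = -1.5 * registry.k_B_cm * T * math.log(m2 / m1)
        assert g2.G - g1.G == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_temperature_rejected(self, registry):
        with pytest.raises(ValueError, match="temperature"):
            rrho_thermo(make_species(), 0.0, registry)

    def test_imaginary_mode_rejected_at_construction(self):
        with pytest.raises(ValueError, match="non-positive"):
            make_species(freqs=(1000.0, -50.0))


class TestBoltzmann:
    def test_published_electronic_ratios_at_450K(self, registry):
        rel = {"EA": 0.0, "EAc": 250.2, "KA": 287.6, "KI": 542.2}
        report = boltzmann_populations(rel, 450.0, "EA", registry=registry)
        rounded = {s: round_half_away(r, 2) for s, r in report.ratios.items()}
        assert rounded == {"EA": 1.0, "EAc": 0.45, "KA": 0.40, "KI": 0.18}

    def test_high_temperature_limit(self, registry):
        rel = {"A": 0.0, "B": 500.0}
        report = boltzmann_populations(rel, 1e9, "A", registry=registry)
        assert report.ratios["B"] == pytest.approx(1.0, abs=1e-6)

    def test_energy_doubling_equals_half_temperature(self, registry):
        rel = {"A": 0.0, "B": 310.0, "C": 620.0}
        doubled = {s: 2 * e for s, e in rel.items()}
        r1 = boltzmann_populations(doubled, 450.0, "A", registry=registry)
        r2 = boltzmann_populations(rel, 225.0, "A", registry=registry)
        for s in rel:
            assert r1.ratios[s] == pytest.approx(r2.ratios[s], rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        e=st.floats(1.0, 5000.0),
        t1=st.floats(100.0, 400.0),
        dt=st.floats(1.0, 400.0),
    )
    def test_monotonicity_in_energy_and_temperature(self, e, t1, dt):
        rel = {"ref": 0.0, "hi": e, "hi2": e * 1.5}
        r = boltzmann_populations(rel, t1, "ref")
        assert r.ratios["hi2"] < r.ratios["hi"] < 1.0
        warmer = boltzmann_populations(rel, t1 + dt, "ref")
        assert warmer.ratios["hi"] > r.ratios["hi"]

    def test_mole_fractions_reference_independent(self, registry):
        rel = {"A": 0.0, "B": 250.0, "C": 550.0}
        fa = boltzmann_populations(rel, 450.0, "A", registry=registry).mole_fractions
        fb = boltzmann_populations(rel, 450.0, "B", registry=registry).mole_fractions
        for s in rel:
            assert fa[s] == pytest.approx(fb[s], rel=1e-12)

    def test_missing_reference(self, registry):
        with pytest.raises(KeyError, match="Z"):
            boltzmann_populations({"A": 0.0}, 450.0, "Z", registry=registry)


class TestGroupFraction:
    def test_published_enol_amino_fraction(self, registry):
        # the published free-energy population ratios at 450 K enter as data
        ratios = {"EA": 1.00, "EAc": 0.45, "KA": 0.60, "KI": 0.16}
        z = sum(ratios.values())
        rel = {s: -registry.k_B_cm * 450.0 * math.log(r) for s, r in ratios.items()}
        report = boltzmann_populations(rel, 450.0, "EA", basis="free_energy",
                                       registry=registry)
        frac = group_mole_fraction(report, {"EA", "EAc"})
        assert round_half_away(frac, 2) == 0.66
        assert frac == pytest.approx((1.00 + 0.45) / z, rel=1e-10)

    def test_all_species_and_empty_set(self, registry):
        report = boltzmann_populations({"A": 0.0, "B": 100.0}, 300.0, "A", registry=registry)
        assert group_mole_fraction(report, {"A", "B"}) == pytest.approx(1.0)
        assert group_mole_fraction(report, set()) == 0.0

    def test_unknown_member(self, registry):
        report = boltzmann_populations({"A": 0.0}, 300.0, "A", registry=registry)
        with pytest.raises(KeyError, match="Q"):
            group_mole_fraction(report, {"Q"})


class TestTautomerCount:
    def test_cytosine_case(self):
        # 4 tautomeric sites, 2 labile protons
        assert tautomer_count(4, 2) == 6

    def test_boundary_cases(self):
        assert tautomer_count(7, 0) == 1
        assert tautomer_count(7, 7) == 1

    @pytest.mark.parametrize("A,B", [(5, 2), (8, 3), (12, 5), (20, 10)])
    def test_against_subset_enumeration(self, A, B):
        enumerated = sum(1 for _ in itertools.combinations(range(A), B))
        assert tautomer_count(A, B) == enumerated
        assert tautomer_count(A, B) == tautomer_count(A, A - B)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            tautomer_count(3, 4)
        with pytest.raises(ValueError):
            tautomer_count(-1, 0)


class TestZpeOrdering:
    def test_zpe_brings_keto_amino_closer_to_reference(self):
        totals = fixtures.relative_totals()
        dzpe = fixtures.relative_zpe()
        assert totals["KA"] + dzpe["KA"] < totals["KA"]
        # with ZPE, the canonical keto-amino form overtakes the second
        # enol rotamer in stability
        assert totals["KA"] + dzpe["KA"] < totals["EAc"] + dzpe["EAc"]
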