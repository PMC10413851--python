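# pcskit

Post-processing toolkit for composite quantum-chemistry characterization of
gas-phase tautomers: assemble composite electronic energies and geometries,
derive rotational constants and semi-experimental references, evaluate RRHO
Boltzmann populations, and build hybrid anharmonic IR spectra.

## Who this is for

Rotational and vibrational spectroscopists (and the computational chemists
supporting them) who have per-level electronic-structure results in hand —
coupled-cluster and MP2 energies at a few basis sets, harmonic and VPT2
frequency tables, vibrational corrections to rotational constants — and need
the *combination layer*: the arithmetic that turns those components into the
numbers experiments are compared against. The package does not run any
electronic-structure calculation; it makes every derived number reproducible
from its tabulated components.

The bundled fixtures carry the complete benchmark tables for the six
tautomers (and their rotamers) of cytosine plus a uracil validation block,
so the whole pipeline can be exercised end to end on real published data.

## The models

**Composite energies.** The total electronic energy is assembled additively
from a frozen-core explicitly correlated coupled-cluster base value, a
complete-basis-set (CBS) correction, and a core-valence (CV) correction:

    E = E[CCSD(T)-F12/3F12, fc] + ΔE_CBS + ΔE_CV

with the CBS limit from the standard two-point n⁻³ extrapolation of
MP2-F12 energies at basis cardinals n = 3, 4,

    E_CBS = (m³·E_m − n³·E_n) / (m³ − n³),    n = 3, m = 4

and ΔE_CV = E(all-electron) − E(frozen-core) at MP2-F12 in a
core-correlating basis. Geometries are combined the same way, parameter by
parameter in internal coordinates: r = r_base + (r_ae − r_fc).

**Rotational constants.** Equilibrium constants come from the principal
moments of inertia, B_i = h/(8π²I_i). Ground-state and semi-experimental
(SE) constants are related through computed vibrational corrections
ΔB_i^vib = B_i^eq − B_i^0, so B⁰ = B^eq − ΔB^vib and
B^SE = B⁰(exp) + ΔB^vib. Agreement is scored with MUE/MAX statistics over
the three constants, absolutely (MHz) and relative to the reference (%).

**Populations.** Tautomer abundances follow Boltzmann statistics,
ratio = exp(−ΔE/k_B·T) with k_B = 0.6950348 cm⁻¹/K, using composite
electronic energies or RRHO free energies; mole fractions are normalized
ratios. The tautomer count is N_T = A!/B!(A−B)! for B labile protons on A
sites (cytosine: A = 4, B = 2, N_T = 6).

**Hybrid IR.** Anharmonic fundamentals combine a high-level harmonic
frequency with a low-level anharmonic shift,
ν = ω_high + (ν_anh,low − ω_low), falling back to ω_high (with a flag) when
VPT2 collapses on a large-amplitude mode such as amino-group inversion.

## Worked example

Populations of the four most abundant cytosine tautomers at the matrix
deposition temperature, from the bundled composite energies:

```bash
$ pcskit populations --temperature 450 --basis electronic --group EA,EAc
```

prints (abridged):

```json
{
  "ratios": {"EA": 1.0, "EAc": 0.449, "KA": 0.399, "KI": 0.177, "KIc": 0.025},
  "mole_fractions": {"EA": 0.488, "EAc": 0.219, "KA": 0.194, "KI": 0.086, "KIc": 0.012},
  "group": {"members": ["EA", "EAc"], "mole_fraction": 0.707}
}
```

Reading: with electronic energies alone, the trans-enol-amino form (EA) is
the most abundant species in the gas phase at 450 K; the keto-amino form
(KA), the only tautomer seen in solution or the solid state, carries a
ratio of 0.40 — rare tautomers dominate gaseous cytosine. The enol-amino
pair (EA+EAc) holds about 70% of the electronic-energy population; with
free energies it relaxes to 0.66, against 0.70 estimated from matrix IR
band ratios.

The same machinery is callable as a library:

```python
from pcskit import fixtures, boltzmann_populations

totals = fixtures.relative_totals()          # cm^-1, reference EA
report = boltzmann_populations(
    {s: totals[s] for s in ("EA", "EAc", "KA", "KI")}, T=450.0, reference="EA"
)
print({s: round(r, 2) for s, r in report.ratios.items()})
# {'EA': 1.0, 'EAc': 0.45, 'KA': 0.4, 'KI': 0.18}
```

Other subcommands: `composite-energy`, `composite-geometry`, `rotations`,
`se-constants`, `stats`, `hybrid-ir`, and `reproduce-paper`, which
regenerates every benchmark number from the bundled tables in one call.

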