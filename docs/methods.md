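# Methods

This note records the models pcskit implements, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations — including the places where the source
tables are internally inconsistent and what the package does about it.

## Scope

pcskit is a combination layer. Electronic-structure computations (DFT and
coupled-cluster engines, VPT2 force fields, dipole/quadrupole property
evaluations) are upstream: their per-level outputs are this package's
inputs. Everything downstream of those numbers — composite assembly,
rotational-constant bookkeeping, statistics, thermochemistry, populations,
hybrid IR tables — is implemented and tested here.

## Units and constants

The canonical internal energy unit is cm⁻¹, the natural unit for relative
tautomer energies (a few hundred cm⁻¹ ≈ a few kJ/mol) and for everything
spectroscopic. Hartree and kJ/mol are accepted on input.

Two frozen conversion registries exist:

* `codata` (default) — factors derived from the exact SI defining constants
  and the CODATA-2018 hartree and amu: 1 hartree = 219474.6313632 cm⁻¹,
  1 kJ/mol = 83.5934723 cm⁻¹, k_B = 0.6950348004 cm⁻¹/K, and the
  inertia-to-constant factor B·I = 505379.009 MHz·amu·Å².
* `paper` — identical except 1 kJ/mol = 83.59 cm⁻¹ exactly, the rounded
  factor thermochemistry tables print, for bit-for-bit reproduction of
  numbers quoted at that precision.

All factors are computed once at registry construction; no module embeds a
literal conversion constant. Atomic masses (AME2020) ship as a CSV keyed by
element and isotope. Elements default to their principal isotope (¹H, ¹²C,
¹⁴N, ¹⁶O), the main-isotopologue convention of rotational spectroscopy;
the benchmark's own mass convention is not stated anywhere, so the
main-isotopologue choice is adopted as the field norm and recorded here as
inferred. Unknown elements or isotopes raise rather than default.

## Composite energies

The three-term assembly E = E_base + ΔCBS + ΔCV is exact bookkeeping; the
physics is in the ingredients. Numerical notes:

* The two-point extrapolation `(m³E_m − n³E_n)/(m³ − n³)` is algebraically
  exact on any series E(k) = E_CBS + A·k⁻³, and the implementation achieves
  that to machine precision (property-tested). Basis cardinals must differ.
* Whether the extrapolation acts on total energies or correlation-only
  components with a separate reference is a choice upstream codes make and
  the printed correction columns absorb either way. The assembly therefore
  accepts whatever pair the caller designates and records a
  `{total | correlation-only}` flag (default `total`) in the breakdown
  metadata rather than guessing.
* Absolute per-species component energies are not published for the
  bundled benchmark; the fixtures store relative components (vs the
  trans-enol-amino species) and composite assembly is exercised at the
  relative level. Relative energies are gauge-invariant (uniform shifts
  cancel) and antisymmetric under reference swap, both property-tested.
* Working precision is double; comparisons with printed tables round half
  away from zero to 0.1 cm⁻¹, matching the tables' formatting.

The analytic "gradient scheme" — composing composite gradients inside the
optimizer so a single optimization runs on the composite surface — is the
contract upstream codes would implement; it requires modifying the
electronic-structure program and is out of scope here. Its additive
per-parameter surrogate (the "geometry scheme", below) is implemented.

## Composite geometries

The additive combination is applied per internal coordinate, not per
Cartesian component: Cartesian additivity is frame-dependent and breaks
under trivial rotations of one input. The caller supplies a Z-matrix-shaped
internal-coordinate spec (the benchmark does not state which set it used,
so none is auto-generated); all three geometries must share the atom
ordering, validated by element-sequence equality, since silent misalignment
is the dominant practical failure mode.

Dihedral arithmetic is circular: differences are the shortest signed arc
and results wrap to (−180°, 180°], so a base dihedral of 179° shifted by
+3° gives −178° rather than 182°, and an ae/fc pair straddling ±180°
yields the physical few-degree shift, not ±358°.

Reconstruction places atoms sequentially in the local frame of their three
reference atoms (the natural-extension convention). Angles at exactly 0° or
180° make the frame degenerate and raise; the round trip
extract ∘ rebuild = identity holds to 1e-8 (property-tested over random
six-atom chains). Bond lengths must be positive and angles strictly inside
(0°, 180°).

## Rotational constants

Equilibrium constants follow from the mass-weighted inertia tensor:
center-of-mass shift, symmetric eigendecomposition, I_a ≤ I_b ≤ I_c,
B_i = 505379.009/I_i MHz. Eigenvectors get a deterministic orientation
(largest-magnitude component positive) so degenerate tops give reproducible
frames. A collinear geometry without the linear flag raises; with it, the
diverging axis constant is reported as `inf` and the two finite constants
are equal. Frame invariance, the planar identity I_c = I_a + I_b, and the
closed-form diatomic B = K/(μr²) are all property-tested.

The vibrational-correction sign convention is ΔB^vib = B^eq − B⁰. The
source never states it; it is fixed by requiring the published
equilibrium/correction/ground-state triples to close (e.g. 3904.3 − 29.1 =
3875.2 MHz for the keto-amino a-axis), and it makes
B⁰ = B^eq − ΔB^vib and B^SE = B⁰(exp) + ΔB^vib exact inverses
(property-tested).

Error statistics are MUE = mean|ΔB_i|, MAX = max|ΔB_i| over the three
constants, with percentage forms relative to the reference constant.
In the uracil block of the source's method-comparison table, the printed
MUE%/MAX% pair of the two double-hybrid columns is impossible under any
mean/max definition (MUE% 0.63 > MAX% 0.56) — the rows appear transposed —
and the printed MUE 10.4 matches neither the mean (12.9) nor the median of
the recomputed deviations. The implemented definitions are the ones that
reproduce the best-method (composite) columns exactly, which are the
columns the acceptance checks assert; printed statistics of the other
columns are stored in fixtures but not asserted.

A second inconsistency: the semi-experimental row of the cis-enol rotamer
in the same table (3920.1/2040.5/1342.7 MHz) cannot be obtained from the
experimental ground-state constants plus the printed corrections, which
give 3913.4/2038.9/1341.7. The package implements the stated construction
rule — validated to ≤ 0.1 MHz on the other four cytosine species, exactly
at printed precision for the two keto-imino rotamers — and the tests pin
the cis-enol deviation so a silent change would surface. (The printed row
is internally consistent with its own MUE/MAX entries, so it is the
correction pairing, not the statistics, that is off in the source.)

The inertial defect Δ = I_c − I_a − I_b, reconstructed from constants, is
provided as a planarity diagnostic (zero for rigid planar rotors, small
negative for pyramidalized amino groups).

## Thermochemistry and populations

RRHO partition functions in cm⁻¹ throughout: harmonic oscillators measured
from ZPE = ½Σω; classical asymmetric-top rotation with symmetry number σ
(default 1 — all cytosine tautomers are C₁/C_s); Sackur–Tetrode
translation at the 1 bar standard state; electronic degeneracy 1 by
default. G = H − T·S with H including the pV term. Imaginary or negative
frequencies are rejected at construction — they have no RRHO meaning.

Low-frequency modes enter harmonically as-is, with no free-rotor
interpolation: for the one genuine large-amplitude motion in this system
(amino inversion) the harmonic frequency is high enough (250–350 cm⁻¹)
that the harmonic treatment of its *thermodynamic* contribution is
adequate, even though its *spectroscopic* anharmonicity is intractable for
VPT2 (see below). Verified limits: vibrational thermal energy → 0 and
ΔG → ΔE + ΔZPE as T → 0; single-mode internal energy → k_BT at
k_BT = 100ω within 1%; translational ΔG = −(3/2)k_BT·ln(m₂/m₁) exactly.

Populations: ratio_s = exp(−(E_s − E_ref)/k_BT), mole fractions normalized
and reference-independent. With the bundled composite electronic energies
at 450 K the ratios against the trans-enol form round to 1.00/0.45/0.40/
0.18 (cis-enol, keto-amino, keto-imino), and the published free-energy
ratio set gives a combined enol-amino mole fraction of 0.66. "Room
temperature" for free-energy output defaults to 298.15 K
(caller-overridable); the source never states the value it used, and the
free-energy column cannot be reproduced quantitatively anyway because the
frequency sets of two of the five species are unpublished — that column is
therefore consumed as data, never asserted. The relative-ZPE ordering
effect (ZPE pulls the keto-amino form below the cis-enol rotamer) is
asserted as an ordering, not as numbers.

## Hybrid IR spectra

ν_hybrid = ω_high + (ν_anh,low − ω_low), per mode, with intensities carried
unchanged from the high-level harmonic calculation. The fallback policy
returns ω_high (flagged) when the low-level anharmonic fundamental is ≤ 0
or the shift magnitude exceeds 300 cm⁻¹ (caller-overridable). The
threshold reproduces both published amino-inversion rows (anharmonic
values −216 and −710 cm⁻¹; printed hybrids equal to the high-level
harmonics 348 and 266 cm⁻¹); whether the source itself used this rule or
another convention for those two cells is not stated, so the rule is
flagged as inferred. No Fermi-resonance deperturbation is attempted (the
keto-amino carbonyl resonance near 1749 cm⁻¹ is exactly the kind of
feature this layer cannot represent), and matrix shifts are not modelled.

Of the 99 hybrid cells in the three bundled 33-mode tables, 94 (including
both fallback rows) satisfy the tables' own assembly rule exactly under
integer arithmetic. Five cells — modes 5, 6, 25, 26 of the trans-enol
table and mode 20 of the keto-amino table — differ from the rule by +2,
+1, +2, +10 and −10 cm⁻¹ respectively. For each, a single-digit change in
the printed anharmonic column would restore consistency, so these are
treated as misprints in the source: they are catalogued in
`fixtures.KNOWN_HYBRID_DISCREPANCIES`, the load-time consistency check
exempts exactly that set (an unexpected deviation anywhere else is a load
error), and the tests assert both the 94 exact cells and the five
catalogued offsets.

Band assignment is greedy nearest-frequency matching within a window,
stronger computed modes first — the deterministic analogue of manual
spectroscopic practice. It is intentionally simple and documented as
replaceable; a globally optimal assignment would need a cost model the
data does not constrain.

## Fixtures

The bundled tables are transcribed at printed precision; no hidden digits
are invented, so cross-table consistency checks run at 0.1 MHz / 0.1 cm⁻¹.
Every number's provenance key is (table, row, column). Three checks run on
every load: composite totals equal component sums; the computed
ground-state block equals best-equilibrium minus double-hybrid corrections;
hybrid columns obey the assembly rule modulo the catalogued cells. One
experimental free-energy cell (cis-keto-imino) is printed as "not
determined" in the source and is stored as missing, never as zero. One
oddity is transcribed as printed: the keto-imino-cis B3LYP equilibrium
triple in the corrections table duplicates the keto-amino row, almost
certainly a typesetting slip; only that row's correction columns are ever
consumed, and those check out against the semi-experimental block.

## Synthetic generators

Three seeded generators (same seed + spec → byte-identical output):

* `rigid_rotor` — point masses on the principal axes solving the
  closed-form second-moment system for prescribed I_a ≤ I_b ≤ I_c, then
  rigidly rotated/translated. It emulates exact rigid bodies only: no
  vibrational averaging, no isotope effects, no near-degenerate numerical
  noise beyond machine precision. Passing tests show the inertia pipeline
  is exact on rigid bodies, not that real floppy molecules are handled
  beyond what the vibrational-correction bookkeeping expresses.
* `cbs_series` — E(k) = E_CBS + A·k⁻ᵖ (default p = 3). With p = 3 the
  extrapolator must recover E_CBS exactly; with p ≠ 3 the analytic residual
  (sign predictable from A) is what the tests assert. Real correlation
  energies only approximately follow the inverse-cube law, which is why the
  benchmark keeps the extrapolated correction small by using explicitly
  correlated methods; the generator does not emulate that approximation
  error.
* `mode_set` — harmonic/anharmonic mode records with negative-leaning
  shifts and optional injected VPT2 failures, for exercising assembly and
  fallback paths at scale. Shift magnitudes are plausible (tens of cm⁻¹)
  but carry no mode-physics correlation structure.

## Problem sizes and determinism

Everything here is desk-scale arithmetic: the full test suite (unit,
property and reproduction layers, ~170 tests) runs in a few seconds, and
the acceptance script in well under a second, on one CPU. Property tests
use derandomized hypothesis profiles or fixed numpy seeds; all analysis
operations are deterministic, with pseudo-randomness confined to the
synthetic generators.

## Known limitations

* No uncertainty propagation: experimental standard errors are parsed away
  and printed-value rounding is treated as exact at table precision.
* No multi-isotopologue SE structure fitting, centrifugal distortion, or
  hyperfine simulation; quadrupole couplings and dipole moments are carried
  as tabulated values only.
* No anharmonic partition functions, hindered-rotor corrections, or
  solvation — gas-phase RRHO only, matching the benchmark's scope.
* The composite recipes implemented are the energy/geometry combination
  layers described above; other composite families (e.g. W-type schemes)
  are out of scope.
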