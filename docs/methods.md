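# Methods

## The molecular model

The Kaxiras porphyrin is modelled as a fixed 44-heavy-atom graph: four
indole units (atoms N1, C2, C3, C3a, C4, C5, C6, C7, C7a plus the catechol
oxygens O5, O6; 12 intra-unit bonds each) joined by four inter-ring
C2(i)–C7(i+1) bonds in a directed a→b→c→d→a cycle. Geometry, conformers
(including the "open"/"closed" OH rotamers) and point-group symmetry are
deliberately outside the model: every question answered here is graph- or
record-level.

A species is identified by which of the 12 mobile hydrogens are removed
(`aXX_bXX_cXX_dXX` names, digits 1/5/6 for N1/O5/O6). Because the
2,7′-coupling is directional, reversing the ring is **not** an
automorphism; species are deduplicated under the four cyclic rotations
only. The canonical orbit representative is the rotation with the
lexicographically smallest per-unit bitmask 4-tuple (N1→1, O5→2, O6→4).
The literature's printed representatives follow no stated rule, so
equality of species is always tested by orbit equivalence, never by
string comparison. Over all 8⁴ = 4096 per-unit state assignments the
orbit count is (8⁴+8+8²+8)/4 = 1044 by Burnside's lemma, which the suite
checks against direct deduplication.

## Closed-shell character as perfect matching

Each atom demands `valence − σ-degree − attached hydrogens` double bonds
(C:4, N:3, O:2). On this skeleton the demand is always 0 or 1: every ring
carbon demands one; N1/O5/O6 demand one exactly when deprotonated/
dehydrogenated. A Kekulé structure is a perfect matching on the demand-one
atoms using bonds whose two endpoints both demand one. This single rule
covers catechol, o-quinone, quinone-methide and quinone-imine rings with
no per-ring cases, and makes "closed-shell" decidable: a species is
closed-shell iff at least one matching exists. Odd oxidation levels fail
by parity (32 carbons plus an odd number of heteroatoms).

All matchings are enumerated by backtracking rather than via a
maximum-matching algorithm because the *full set* is needed downstream
for circuit search and bond-order export; the counts involved are tiny
(16 structures for the fully reduced form is the maximum encountered).

Enumeration iterates over per-unit states (8 per unit, 4096 assignments)
rather than hydrogen placements (2¹²), filters by total level and a
per-unit oxidation cap, tests matching feasibility once per rotation
orbit, and canonicalizes. The default cap of two removed hydrogens per
unit reflects that the three-electron-oxidized unit is a high-energy site
not used when building start structures at the lower levels; it is
admitted on request (`include_three_electron_blocks`), which is how the
levels 10 and 12 are proven empty rather than assumed so.

A second, independent route composes single-unit **building blocks**
(unit state + dangling bond orders at C2/C7, themselves derived from
single-unit matching feasibility, never hard-coded) around the directed
4-cycle. Both routes decide the same feasibility predicate — each
inter-ring bond order splits the whole-graph matching into independent
single-unit problems — and the suite asserts their agreement on all 4096
assignments and at every census level. The derived library has the
expected shape: one reduced block, four one-electron blocks (states {N1}
and {O6} only — {O5} admits no matching), three two-electron
(single, single) blocks, one two-electron (double, double) block, and
exactly one three-electron block, whose dangling double bond can only sit
at the 7-position.

## Macrocyclic conjugation and the Hückel rule

A macrocyclic conjugation circuit is a cycle through all four inter-ring
bonds whose edges alternate strictly double/single with respect to some
Kekulé structure. Within each unit a circuit follows one of the (at most
four) simple C7→C2 paths, so the search takes the cyclic product of
per-unit paths against every matching and filters by alternation —
exhaustive by construction. The π-electron count is the number of atoms
on the circuit, equal to twice its double-bond count; `huckel_class`
labels counts ≡ 2 (mod 4) aromatic and multiples of 4 antiaromatic.

Two emergent regularities are asserted over the entire census rather than
assumed: a circuit exists iff all four units are in states {N1}, {O6} or
{N1,O6}, and the count then decomposes as a per-unit sum 7/5/4 for
{N1}/{O6}/{N1,O6} (e.g. 4+5+4+5 = 18 for `a16_b6_c16_d6`). The engine
returns a *set* of counts per species, because uniqueness across
alternative circuits is an observed property of this skeleton, not a
contract; on the enumerated censuses the set is always a singleton when
non-empty.

## Free-energy post-processing

`SpeciesRecord` carries electronic energies (vacuum and solution),
nonelectrostatic solvation and thermal (RRHO) corrections in hartree,
orbital energies, transition lines (eV, oscillator strength) and harmonic
modes (cm⁻¹, intensity). Three composite schemes are exposed — `vacuum`,
`vacuum_rrho`, `smd_rrho` — because published disproportionation tables
do not always state whether thermal corrections entered the in-vacuo
column; providing both costs nothing.

Conversions live in one constants table (627.5095 kcal/mol and 27.2114 eV
per hartree; R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹, so RT·ln 10 = 1.364
kcal/mol at the default 298.15 K).

* **Relative stabilities**: ΔG against the level minimum, Boltzmann
  weights ∝ exp(−ΔG/RT) normalized to one; sorted, ties broken by name.
* **pKa**: per reference pair, pKa = pKa_ref + (ΔG − ΔG_ref)/(RT ln 10);
  the proton's solvation free energy cancels in the difference and is
  never taken from an absolute value. The aggregate is the arithmetic
  mean with the min–max spread, since reference sets are user-supplied.
* **Disproportionation**: the smallest balanced m KP-n → x KP-p + y KP-q
  has x = (q−n)/g, y = (n−p)/g, g = gcd; ΔG uses one representative
  record per level (the scheme-selected minimum is the intended choice;
  any record can be supplied). Per-mole values divide by m, matching the
  fractional-coefficient convention; comproportionation is the negative.
* **HOMO–LUMO gap**: lowest virtual minus highest occupied orbital,
  reported in eV.

## Spectrum synthesis

"Line width" is interpreted as the Gaussian **full width at half
maximum** and is an explicit parameter, since the convention is not
universal. UV–Vis: transitions at or above the 5.6 eV cutoff are dropped;
each retained line contributes f·exp(−(E−E₀)²/2σ²) evaluated at
E(λ) = 1239.842/λ on a 200–1400 nm, 1 nm grid. No Jacobian factor is
applied in the wavelength conversion (the common quantum-chemistry
visualization convention); a `jacobian=True` switch applies E²/1239.842
for users who want the density-consistent form. IR: frequencies are
scaled by 0.9547 then broadened with a 20 cm⁻¹ FWHM kernel on a
400–2000 cm⁻¹, 1 cm⁻¹ grid. Amplitudes are arbitrary units; no molar
absorptivity normalization is attempted, and vibronic structure is out of
scope. Linearity, isolated-line peak location (within one grid step) and
the energy-integral ∝ Σf identity are asserted in the suite.

## Synthetic records

The generator produces honest fakes (`provenance="synthetic"`): records
whose *qualitative* structure matches what is known about the series,
never claimed DFT values. The `paper_like` preset uses one representative
(most stable) tautomer per level — a0_b0_c0_d0, a6_b0_c0_d0, a6_b6_c0_d0,
a16_b6_c6_d0, a16_b6_c16_d6, a16_b56_c16_d56 — with designed composite
free-energy offsets relative to KP-Red:

| level | vacuum (kcal/mol) | water (kcal/mol) |
|------:|------------------:|-----------------:|
| 1     | 8.0               | 1.5              |
| 2     | 12.0              | 4.0              |
| 4     | 18.0              | 9.0              |
| 6     | 15.0              | 10.0             |
| 8     | 45.0              | 35.0             |

These values were chosen once so that in vacuo every intermediate level
(1, 2, 4) disproportionates spontaneously toward KP-Red + KP-6e, KP-6e →
KP-Red + KP-8e is strongly endoergonic, and in water (the `smd_rrho`
scheme on the same records) KP-1e disproportionation and KP-2e →
KP-Red + KP-4e turn slightly endoergonic while the overall KP-2e →
KP-Red + KP-6e conversion stays spontaneous. The absolute anchor
(−1500 hartree) and the roughly constant thermal/nonelectrostatic
components cancel in every balanced reaction since m = x + y. Gaussian
noise of 0.5 kcal/mol on the energies keeps fixtures non-degenerate; the
draw is rejected and redrawn deterministically (sub-seeded attempts)
until the designed sign structure holds under all three schemes, with a
final assertion as a guard. Gap targets (3.6/3.3/1.7/1.4/1.6/1.8 eV for
levels 0–8) echo the qualitative trend of a mid-series gap minimum;
orbital lists realize the stored gap exactly so round-trip tests are
sharp. Transition lists sit below the UV cutoff with the lowest line
tracking the gap; oxidized species get strong unscaled 1700–1770 cm⁻¹
modes so scaled IR curves show the carbonyl-region features.

What the fixtures do **not** emulate: absolute DFT energies, real
oscillator-strength patterns (Soret/Q intensity ratios), orbital-symmetry
structure, conformer multiplicity, and any geometry dependence. Passing
tests therefore demonstrate the correctness of the post-processing
algebra and sign logic, not agreement with electronic-structure data.

## Interfaces and numerical choices

Records travel as one versioned JSON document (`kporph-records-1`),
normalized on write (sorted keys) so write∘read is the identity; unknown
fields are preserved. SDF export writes a V2000 table with bond orders
from the lexicographically first Kekulé structure and a schematic radial
2-D layout (flagged in the comment line); standard implicit-valence rules
then imply the correct hydrogen count at every atom. Ties anywhere
(matching order, table sorting) are broken by deterministic
lexicographic keys, so identical invocations produce identical bytes.

Problem sizes throughout are desk-scale by design: 4096 state
assignments, ≤16 matchings per species, ≤256 candidate circuits per
matching; the whole suite and the acceptance script run in seconds.

## Known limitations

* No electronic-structure computation, geometries, point groups, bond
  lengths, NICS/HOMA aromaticity indices or resonance energies.
* Open-shell species are enumerated without valence analysis (radical
  Kekulé structures are undefined here), and their motifs are rejected.
* The pKa estimator is only as good as the supplied reference pairs; no
  reference set ships with the package.
* Real quantum-chemistry log parsing is a documented hook (the record
  schema), not an implemented reader.
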