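# kporph

Tautomer combinatorics and redox/spectral post-processing for the
**Kaxiras porphyrin (KP)** — the cyclic tetramer of 5,6-dihydroxyindole
(DHI, the eumelanin building block) joined head-to-tail by 2,7′-bonds into a
porphyrin-like macrocycle.

KP is a catechol-controlled redox platform: removing *n* mobile hydrogens
(from N1, O5–H, O6–H of the four indole units, 12 positions in all)
together with *n* electrons gives the KP-*n*e oxidation states, each with a
rich tautomer landscape. This package answers, at desk scale, the
combinatorial and post-processing questions that frame that landscape:

* **Which tautomers are closed-shell?** A species is closed-shell iff a
  Kekulé structure exists — a perfect matching on the atoms demanding one
  double bond (`demand = valence − σ-degree − attached H`). Exhaustive
  enumeration with cyclic-rotation deduplication yields the censuses
  1 / 7 / 49 / 74 / 24 at levels 0/2/4/6/8, and proves that levels 10 and
  12 admit no closed-shell structure at all.
* **Which are porphyrin-aromatic?** Macrocyclic conjugation circuits —
  cycles through all four inter-ring bonds with strict double/single
  alternation — are found exhaustively; their atom count is the π-electron
  count, classified by the Hückel 4*n*+2 rule (18 π aromatic, 16/20 π
  antiaromatic).
* **What do the energies imply?** Boltzmann weights, pKa by linear
  free-energy comparison with reference acid/base pairs, balanced
  disproportionation reactions *m* KP-*n*e → *x* KP-*p*e + *y* KP-*q*e
  with total and per-mole ΔG, and HOMO–LUMO gaps — all operating on
  quantum-chemistry summary records (`SpeciesRecord`), real or synthetic.
* **What do the spectra look like?** UV–Vis curves from TD-DFT-style
  transition lists (0.25 eV Gaussian FWHM, 5.6 eV cutoff, wavelength
  conversion via E = 1239.842/λ) and IR curves from harmonic modes
  (0.9547 frequency scaling, 20 cm⁻¹ FWHM).

A seed-deterministic synthetic-data module generates records with the
known qualitative redox structure of the series (KP-6e global stability,
spontaneous in-vacuo disproportionation of intermediate states,
near-neutral KP-1e disproportionation in water), so every downstream stage
is fully testable without any DFT computation.

## Worked example

```python
import kporph as kp

# the six-electron oxidation level: 74 distinct closed-shell tautomers
census = kp.enumerate_closed_shell(6)
print(len(census))                       # 74

# its most stable tautomer is porphyrin-aromatic
name = kp.parse_name("a16_b6_c16_d6")
print(kp.macrocyclic_pi_counts(name))    # frozenset({18})
print(kp.huckel_class(18))               # 'aromatic'
circuit = kp.macrocyclic_circuits(name)[0]
print(len(circuit.circuit_double_bonds()))  # 9

# synthetic records reproduce the redox sign structure
records = {r.level: r for r in kp.make_scenario("paper_like", seed=1)}
rxn = kp.balance_disproportionation(2, 0, 6)
print(rxn.coefficients)                  # (3, 2, 1): 3 KP-2e -> 2 KP-Red + KP-6e
print(kp.disproportionation_dG(records, rxn, scheme="vacuum"))
# (-20.61, -6.87) kcal/mol: spontaneous in vacuo
print(kp.disproportionation_dG(records, rxn, scheme="smd_rrho"))
# (-1.32, -0.44) kcal/mol: still spontaneous, but barely, in water
```

The numbers read as follows: 74 tautomers survive rotation-deduplication at
KP-6e; `a16_b6_c16_d6` carries one macrocyclic circuit family with nine
conjugated double bonds, an 18 π-electron aromatic system; and the
synthetic scenario makes the 3 KP-2e → 2 KP-Red + KP-6e conversion
exergonic by 6.87 kcal per mole of reactant in vacuo but only 0.44 in
water.

A command-line interface mirrors the library:

```bash
kporph enumerate --level 4 --out census.csv       # 49 rows with motif tags
kporph aromaticity --name a16_b6_c16_d6           # pi counts + witness circuit
kporph fixtures --preset paper_like --seed 1 --out records.json
kporph thermo --records records.json --report dispro --scheme vacuum --out dG.csv
kporph spectra uv --records records.json --species a16_b6_c16_d6 --out uv.csv
kporph export --name a0_b0_c0_d0 --out kp_red.sdf # SDF V2000, Kekulé bond orders
```

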