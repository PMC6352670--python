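"""Free-energy post-processing: stabilities, pKa, disproportionation, gaps.

Operates on :class:`SpeciesRecord` summaries of quantum-chemistry output
(real or synthetic); no electronic-structure computation happens here.
Energies enter in hartree and leave in kcal/mol (or eV for orbital gaps)
through a single constants table.

Composite free-energy schemes
-----------------------------
``vacuum``
    gas-phase electronic energy only;
``vacuum_rrho``
    plus the rigid-rotor/harmonic-oscillator thermal correction;
``smd_rrho``
    solution-phase electronic energy plus SMD nonelectrostatic terms plus
    the thermal correction (the ΔG_SMD,RRHO composite).

pKa estimation is relative: for each reference acid/base pair,
``pKa = pKa_ref + (ΔG_target − ΔG_ref) / (RT ln 10)``, so the proton's
solvation free energy cancels and is never taken from an absolute value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import gcd
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "HARTREE_TO_KCAL",
    "HARTREE_TO_EV",
    "R_KCAL",
    "rt_ln10",
    "Scheme",
    "SpeciesRecord",
    "ReactionSpec",
    "composite_free_energy",
    "relative_energies_and_weights",
    "estimate_pka",
    "balance_disproportionation",
    "disproportionation_dG",
    "homo_lumo_gap",
]

# single conversion-constants table (CODATA)
HARTREE_TO_KCAL = 627.5094740631
HARTREE_TO_EV = 27.211386245988
R_KCAL = 1.987204258640832e-3  # kcal mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.15  # K


def rt_ln10(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT·ln 10 in kcal/mol (1.364 kcal/mol at 298.15 K)."""
    return R_KCAL * temperature * math.log(10.0)


Scheme = Literal["vacuum", "vacuum_rrho", "smd_rrho"]


class SpeciesRecord(BaseModel):
    """Quantum-chemistry summary for one species, real or synthetic.

    All energies are in hartree; transition energies in eV; harmonic
    frequencies in cm^-1.  ``provenance`` marks synthetic fixtures.
    Unknown extra fields are preserved on round-trip.
    """

    model_config = ConfigDict(extra="allow", frozen=False)

    name: str
    level: int = Field(ge=0, le=12)
    charge: int = 0
    electronic_energy_vacuum: Optional[float] = None
    electronic_energy_solution: Optional[float] = None
    nonelectrostatic_solvation: Optional[float] = None
    thermal_free_energy_correction: Optional[float] = None
    occupied_orbital_energies: Optional[list[float]] = None
    virtual_orbital_energies: Optional[list[float]] = None
    transitions: Optional[list[tuple[float, float]]] = None
    modes: Optional[list[tuple[float, float]]] = None
    provenance: str = "unspecified"

    @model_validator(mode="after")
    def _check_physics(self) -> "SpeciesRecord":
        if self.occupied_orbital_energies is not None and not self.occupied_orbital_energies:
            raise ValueError("occupied orbital list present but empty")
        for energy, strength in self.transitions or []:
            if strength < 0:
                raise ValueError(f"negative oscillator strength {strength} at {energy} eV")
        for freq, intensity in self.modes or []:
            if intensity < 0:
                raise ValueError(f"negative IR intensity {intensity} at {freq} cm^-1")
            if freq <= 0:
                raise ValueError(f"non-positive harmonic frequency {freq} cm^-1")
        return self


@dataclass(frozen=True)
class ReactionSpec:
    """A balanced disproportionation: m KP-n -> x KP-p + y KP-q.

    Mass balance m = x + y and redox balance m·n = x·p + y·q hold exactly;
    the coefficient triple is coprime.
    """

    reactant_level: int
    product_levels: tuple[int, int]
    coefficients: tuple[int, int, int]

    def __post_init__(self) -> None:
        m, x, y = self.coefficients
        n = self.reactant_level
        p, q = self.product_levels
        if m != x + y or m * n != x * p + y * q:
            raise ValueError(f"unbalanced reaction {m} KP-{n} -> {x} KP-{p} + {y} KP-{q}")


def composite_free_energy(record: SpeciesRecord, scheme: Scheme) -> float:
    """Composite free energy (hartree) for a record under a scheme.

    Raises ``ValueError`` naming the first missing component.
    """

    def need(value: Optional[float], field_name: str) -> float:
        if value is None:
            raise ValueError(
                f"record {record.name!r} lacks {field_name!r} required by scheme {scheme!r}"
            )
        return value

    if scheme == "vacuum":
        return need(record.electronic_energy_vacuum, "electronic_energy_vacuum")
    if scheme == "vacuum_rrho":
        return need(record.electronic_energy_vacuum, "electronic_energy_vacuum") + need(
            record.thermal_free_energy_correction, "thermal_free_energy_correction"
        )
    if scheme == "smd_rrho":
        return (
            need(record.electronic_energy_solution, "electronic_energy_solution")
            + need(record.nonelectrostatic_solvation, "nonelectrostatic_solvation")
            + need(record.thermal_free_energy_correction, "thermal_free_energy_correction")
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def relative_energies_and_weights(
    records: Sequence[SpeciesRecord],
    scheme: Scheme = "vacuum",
    temperature: float = DEFAULT_TEMPERATURE,
) -> pd.DataFrame:
    """Relative free energies (kcal/mol) and Boltzmann weights at one level.

    The minimum has relative energy zero; weights are proportional to
    exp(−ΔG/RT) and sum to one.  Sorted ascending by relative energy, ties
    broken by name.
    """
    if not records:
        raise ValueError("need at least one record")
    levels = {r.level for r in records}
    if len(levels) > 1:
        raise ValueError(f"records span several oxidation levels: {sorted(levels)}")
    energies = {
        r.name: composite_free_energy(r, scheme) * HARTREE_TO_KCAL for r in records
    }
    g_min = min(energies.values())
    rel = {name: g - g_min for name, g in energies.items()}
    rt = R_KCAL * temperature
    boltz = {name: math.exp(-dg / rt) for name, dg in rel.items()}
    z = sum(boltz.values())
    rows = sorted(
        (
            {"name": name, "rel_energy_kcal": dg, "weight": boltz[name] / z}
            for name, dg in rel.items()
        ),
        key=lambda row: (row["rel_energy_kcal"], row["name"]),
    )
    return pd.DataFrame(rows, columns=["name", "rel_energy_kcal", "weight"])


def estimate_pka(
    target_dG_kcal: float,
    references: Sequence[tuple[float, float]],
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[float, float, list[float]]:
    """pKa by linear free-energy comparison with reference AH/A⁻ pairs.

    ``references`` holds ``(deprotonation ΔG in kcal/mol, known pKa)``
    pairs.  Per reference, ``pKa_i = pKa_ref + (ΔG − ΔG_ref)/(RT ln 10)``.
    Returns ``(mean, min-max spread, per-reference estimates)``.
    """
    if not references:
        raise ValueError("at least one reference acid/base pair is required")
    denom = rt_ln10(temperature)
    estimates = [
        pka_ref + (target_dG_kcal - dg_ref) / denom for dg_ref, pka_ref in references
    ]
    return (
        sum(estimates) / len(estimates),
        max(estimates) - min(estimates),
        estimates,
    )


def balance_disproportionation(n: int, p: int, q: int) -> ReactionSpec:
    """Smallest balanced reaction m KP-n -> x KP-p + y KP-q.

    Requires p < n < q; the unique coprime solution is
    x = (q−n)/g, y = (n−p)/g with g = gcd(q−n, n−p) and m = x + y.
    """
    if not p < n < q:
        raise ValueError(
            f"reactant level must lie strictly between product levels, got {p} < {n} < {q}"
        )
    g = gcd(q - n, n - p)
    x, y = (q - n) // g, (n - p) // g
    m = x + y
    if gcd(gcd(m, x), y) != 1:  # pragma: no cover - guaranteed by construction
        raise AssertionError("coefficient triple not coprime")
    return ReactionSpec(reactant_level=n, product_levels=(p, q), coefficients=(m, x, y))


def disproportionation_dG(
    records_by_level: Mapping[int, SpeciesRecord],
    spec: ReactionSpec,
    scheme: Scheme = "vacuum",
) -> tuple[float, float]:
    """Total and per-mole-of-reactant reaction free energies (kcal/mol).

    ΔG = x·G(p) + y·G(q) − m·G(n); the per-mole value divides by m (the
    fractional-coefficient convention).  The comproportionation ΔG is the
    negative.  Raises ``KeyError`` naming any missing level.
    """
    n = spec.reactant_level
    p, q = spec.product_levels
    for level in (n, p, q):
        if level not in records_by_level:
            raise KeyError(f"no species record supplied for oxidation level {level}")
    g = {
        lvl: composite_free_energy(records_by_level[lvl], scheme) * HARTREE_TO_KCAL
        for lvl in (n, p, q)
    }
    m, x, y = spec.coefficients
    total = x * g[p] + y * g[q] - m * g[n]
    return total, total / m


def homo_lumo_gap(record: SpeciesRecord) -> float:
    """HOMO-LUMO gap in eV: lowest virtual minus highest occupied orbital."""
    if not record.occupied_orbital_energies or not record.virtual_orbital_energies:
        raise ValueError(
            f"record {record.name!r} lacks occupied and/or virtual orbital energies"
        )
    homo = max(record.occupied_orbital_energies)
    lumo = min(record.virtual_orbital_energies)
    return (lumo - homo) * HARTREE_TO_EV
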