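"""Kekulé structures, macrocyclic conjugation circuits and the Hückel rule.

A KP tautomer is closed-shell iff a valence structure exists in which every
atom's double-bond demand is satisfied.  Demand follows a single rule:

    demand = valence - sigma-degree - attached hydrogens

with valences C:4, N:3, O:2.  Every ring carbon then demands exactly one
double bond, while N1/O5/O6 demand one iff their mobile hydrogen has been
removed.  A Kekulé structure is therefore a perfect matching on the
demand-one atom set, using only graph bonds whose two endpoints both demand
a double bond.  One rule covers catechol, o-quinone, quinone-methide and
quinone-imine rings without special cases.

Macrocyclic conjugation circuits — cycles through all four inter-ring bonds
whose edges alternate strictly double/single with respect to some Kekulé
structure — carry the porphyrin-type aromaticity of the system; their atom
count is the pi-electron count classified by the Hückel 4n+2 rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx

from .skeleton import (
    Atom,
    Bond,
    PorphyrinGraph,
    TautomerName,
    UNITS,
    build_skeleton,
)

__all__ = [
    "KekuleStructure",
    "ConjugationCircuit",
    "atom_double_bond_demand",
    "kekule_structures",
    "has_kekule_structure",
    "macrocyclic_circuits",
    "macrocyclic_pi_counts",
    "huckel_class",
]

#: Standard valences used by the demand rule.
_VALENCE = {"N": 3, "C": 4, "O": 2}

#: Ring positions that always carry one CH hydrogen.
_CH_POSITIONS = frozenset({"C3", "C4"})


@dataclass(frozen=True)
class KekuleStructure:
    """One closed-shell valence structure: the set of double bonds.

    ``double_bonds`` is a perfect matching on the atoms demanding one
    double bond; atoms with demand zero touch no member.
    """

    name: TautomerName
    double_bonds: frozenset

    def sort_key(self) -> tuple:
        return tuple(sorted(tuple(sorted(b)) for b in self.double_bonds))


@dataclass(frozen=True)
class ConjugationCircuit:
    """A macrocyclic alternating circuit witnessing porphyrin conjugation.

    ``atoms`` is the cyclic atom sequence; consecutive atoms are bonded and
    the bonds alternate strictly double/single with respect to
    ``structure``.  The pi-electron count equals the number of atoms on the
    circuit, which equals twice the number of on-circuit double bonds.
    """

    atoms: tuple[Atom, ...]
    structure: KekuleStructure

    @property
    def pi_electrons(self) -> int:
        return len(self.atoms)

    def circuit_bonds(self) -> tuple[Bond, ...]:
        n = len(self.atoms)
        return tuple(
            frozenset({self.atoms[i], self.atoms[(i + 1) % n]}) for i in range(n)
        )

    def circuit_double_bonds(self) -> tuple[Bond, ...]:
        return tuple(
            b for b in self.circuit_bonds() if b in self.structure.double_bonds
        )


def atom_double_bond_demand(name: TautomerName, atom: Atom) -> int:
    """Number of double bonds atom must form (0 or 1) in this tautomer."""
    unit, label = atom
    element = label[0]
    graph = _skeleton()
    sigma = len(graph.neighbors(atom))
    if label in _CH_POSITIONS:
        n_h = 1
    elif label in ("N1", "O5", "O6"):
        removed = name.removed[UNITS.index(unit)]
        n_h = 0 if label in removed else 1
    else:
        n_h = 0
    demand = _VALENCE[element] - sigma - n_h
    if demand not in (0, 1):
        raise AssertionError(f"impossible demand {demand} at {atom}")
    return demand


@lru_cache(maxsize=1)
def _skeleton() -> PorphyrinGraph:
    return build_skeleton()


def _required_atoms(name: TautomerName) -> frozenset:
    graph = _skeleton()
    return frozenset(
        a for a in graph.atoms if atom_double_bond_demand(name, a) == 1
    )


def _demand_adjacency(required: frozenset) -> dict[Atom, tuple[Atom, ...]]:
    graph = _skeleton()
    adj: dict[Atom, list[Atom]] = {a: [] for a in required}
    for bond in graph.bonds:
        x, y = tuple(bond)
        if x in required and y in required:
            adj[x].append(y)
            adj[y].append(x)
    return {a: tuple(sorted(ns)) for a, ns in adj.items()}


def kekule_structures(name: TautomerName) -> tuple[KekuleStructure, ...]:
    """All Kekulé structures of a tautomer, sorted deterministically.

    Enumerates every perfect matching on the demand-one atom set by
    backtracking (the graph has at most 44 relevant atoms and the matching
    counts are tiny).  Returns the empty tuple iff the species is
    open-shell.
    """
    required = _required_atoms(name)
    if len(required) % 2:
        return ()
    adj = _demand_adjacency(required)
    out: list[frozenset] = []

    def backtrack(remaining: frozenset, chosen: frozenset) -> None:
        if not remaining:
            out.append(chosen)
            return
        atom = min(remaining)
        for partner in adj[atom]:
            if partner in remaining:
                bond = frozenset({atom, partner})
                backtrack(remaining - {atom, partner}, chosen | {bond})

    backtrack(required, frozenset())
    structures = tuple(
        sorted(
            (KekuleStructure(name=name, double_bonds=m) for m in out),
            key=KekuleStructure.sort_key,
        )
    )
    return structures


def has_kekule_structure(name: TautomerName) -> bool:
    """Closed-shell test: does any perfect matching exist?  (Early exit.)"""
    required = _required_atoms(name)
    if len(required) % 2:
        return False
    adj = _demand_adjacency(required)

    def feasible(remaining: frozenset) -> bool:
        if not remaining:
            return True
        atom = min(remaining)
        return any(
            feasible(remaining - {atom, partner})
            for partner in adj[atom]
            if partner in remaining
        )

    return feasible(required)


@lru_cache(maxsize=8)
def _unit_c7_to_c2_paths(unit: str) -> tuple[tuple[Atom, ...], ...]:
    """Simple C7 -> C2 paths inside one unit's subgraph (at most four)."""
    graph = _skeleton()
    sub = nx.Graph()
    for bond in graph.bonds:
        x, y = tuple(bond)
        if x[0] == unit and y[0] == unit:
            sub.add_edge(x, y)
    paths = nx.all_simple_paths(sub, (unit, "C7"), (unit, "C2"))
    return tuple(sorted(tuple(p) for p in paths))


def macrocyclic_circuits(name: TautomerName) -> tuple[ConjugationCircuit, ...]:
    """All macrocyclic alternating conjugation circuits of a tautomer.

    For each Kekulé structure, every cycle through the four inter-ring
    bonds is assembled as the cyclic product of per-unit simple C7->C2
    paths, then filtered for strict double/single alternation.  Exhaustive
    by construction.  Raises ``ValueError`` on open-shell input.
    """
    structures = kekule_structures(name)
    if not structures:
        raise ValueError(f"{name} is open-shell: no valence structure exists")
    path_choices = [_unit_c7_to_c2_paths(u) for u in UNITS]
    circuits: list[ConjugationCircuit] = []
    seen: set[tuple] = set()
    for structure in structures:
        for combo in itertools.product(*path_choices):
            atoms = tuple(itertools.chain.from_iterable(combo))
            n = len(atoms)
            kinds = [
                frozenset({atoms[i], atoms[(i + 1) % n]}) in structure.double_bonds
                for i in range(n)
            ]
            if all(kinds[i] != kinds[(i + 1) % n] for i in range(n)):
                key = (atoms, structure.sort_key())
                if key not in seen:
                    seen.add(key)
                    circuits.append(ConjugationCircuit(atoms=atoms, structure=structure))
    return tuple(circuits)


def macrocyclic_pi_counts(name: TautomerName) -> frozenset:
    """Set of pi-electron counts over all macrocyclic conjugation circuits.

    Empty iff no macrocyclic conjugated circuit exists (porphyrin-type
    aromaticity absent, e.g. the a16_b56_c16_d56 tautomer of KP-8e).
    """
    return frozenset(c.pi_electrons for c in macrocyclic_circuits(name))


def huckel_class(pi_electrons: int) -> str:
    """Hückel 4n+2 classification of an even pi-electron count.

    Returns ``"aromatic"`` for counts congruent to 2 mod 4 (18, 22, 26, ...)
    and ``"antiaromatic"`` for multiples of 4 (16, 20, 24, ...).
    """
    if pi_electrons <= 0 or pi_electrons % 2:
        raise ValueError(f"pi-electron count must be positive and even, got {pi_electrons}")
    return "aromatic" if pi_electrons % 4 == 2 else "antiaromatic"
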