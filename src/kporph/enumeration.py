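"""Closed-shell tautomer enumeration with cyclic-symmetry deduplication.

The generation problem: given an oxidation level ``n`` (hydrogens removed
from the 12 mobile sites), list every distinct closed-shell tautomer.  Two
routes are provided and kept deliberately independent:

1. **Whole-graph route** (the default): iterate over per-unit removed-H
   states (8 per unit, 4096 assignments), filter by level and per-unit
   oxidation cap, test closed-shell character by perfect-matching
   feasibility on the full 44-atom graph, and deduplicate under the four
   cyclic rotations.  Brute force at this size is fast and auditable.

2. **Building-block route** (:func:`enumerate_by_block_composition`): derive
   the library of admissible single-unit building blocks — each a unit
   state plus dangling bond orders at the 2- and 7-positions — and accept a
   state assignment iff blocks can be chosen with consistent bond orders
   around the directed a->b->c->d->a cycle.  This mirrors the constructive
   procedure a chemist would use and serves as a cross-check of route 1.

Default per-unit cap is two removed hydrogens; the unique three-electron
block (state {N1,O5,O6}, dangling double at C7) is a high-energy site and
is only admitted on request.  Even with it, levels 10 and 12 admit no
closed-shell structure: there is no way to close the macrocycle with two
three-electron units and two two-electron units, nor with three
three-electron units and a one-electron unit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

from .skeleton import (
    MOBILE_SITE_LABELS,
    TautomerName,
    UNITS,
    build_skeleton,
    canonical_form,
)
from . import valence

__all__ = [
    "BuildingBlock",
    "TautomerCensus",
    "MOTIF_TAGS",
    "enumerate_closed_shell",
    "enumerate_open_shell",
    "enumerate_by_block_composition",
    "is_closed_shell",
    "derive_block_library",
    "classify_motifs",
]

#: All 8 removed-H states a single unit can adopt.
UNIT_STATES: tuple[frozenset, ...] = tuple(
    frozenset(c)
    for r in range(4)
    for c in itertools.combinations(MOBILE_SITE_LABELS, r)
)

MOTIF_TAGS = (
    "single-ring-localized",
    "interring-pair",
    "three-ring-chain",
    "macrocyclic-conjugated",
    "alternating-localized-quinonoid",
)


@dataclass(frozen=True)
class BuildingBlock:
    """A single DHI unit at a given oxidation state with its dangling bonds.

    ``dangling_2`` / ``dangling_7`` give the bond order ("single" or
    "double") the unit presents externally at C2 and C7.  A block is
    admissible iff the one-unit subgraph admits a perfect matching on its
    demand-one atoms once the dangling double bonds are satisfied
    externally; parity forces |state| + number of dangling doubles even.
    """

    state: frozenset
    dangling_2: str
    dangling_7: str

    @property
    def unit_oxidation(self) -> int:
        return len(self.state)


@dataclass(frozen=True)
class TautomerCensus:
    """The deduplicated tautomer list at one oxidation level."""

    level: int
    names: frozenset
    counts_by_motif: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.names)

    def sorted_names(self) -> tuple[TautomerName, ...]:
        return tuple(sorted(self.names))


# ---------------------------------------------------------------------------
# building-block derivation

def _single_unit_block_feasible(state: frozenset, dangling_2: str, dangling_7: str) -> bool:
    """Matching feasibility of one unit with external dangling constraints."""
    graph = build_skeleton()
    unit = UNITS[0]
    name = TautomerName((frozenset(state), frozenset(), frozenset(), frozenset()))
    required = {
        a
        for a in graph.atoms
        if a[0] == unit and valence.atom_double_bond_demand(name, a) == 1
    }
    # a dangling double bond satisfies the junction carbon's demand externally
    if dangling_2 == "double":
        required.discard((unit, "C2"))
    if dangling_7 == "double":
        required.discard((unit, "C7"))
    if len(required) % 2:
        return False
    adj: dict = {a: [] for a in required}
    for bond in graph.bonds:
        x, y = tuple(bond)
        if x in required and y in required:
            adj[x].append(y)
            adj[y].append(x)

    def feasible(remaining: frozenset) -> bool:
        if not remaining:
            return True
        atom = min(remaining)
        return any(
            feasible(remaining - {atom, partner})
            for partner in adj[atom]
            if partner in remaining
        )

    return feasible(frozenset(required))


def derive_block_library(include_three_electron_blocks: bool = False) -> frozenset:
    """Derive all admissible building blocks from matching feasibility.

    The standard library has nine members: the reduced unit (single,
    single); four one-electron blocks (state {N1} or {O6}, dangling double
    at either junction — never {O5}); the three two-electron
    (single, single) blocks, i.e. o-quinone {O5,O6}, quinone methide
    {N1,O6} and quinone imine {N1,O5}; and the one two-electron
    (double, double) block {N1,O6}.  With the flag, exactly one
    three-electron block is added: {N1,O5,O6} with its dangling double at
    the 7-position.
    """
    max_ox = 3 if include_three_electron_blocks else 2
    blocks = set()
    for state in UNIT_STATES:
        if len(state) > max_ox:
            continue
        for d2, d7 in itertools.product(("single", "double"), repeat=2):
            if _single_unit_block_feasible(state, d2, d7):
                blocks.add(BuildingBlock(state=state, dangling_2=d2, dangling_7=d7))
    return frozenset(blocks)


def enumerate_by_block_composition(
    level: int,
    max_unit_oxidation: int = 2,
    include_three_electron_blocks: bool = False,
) -> frozenset:
    """Census via explicit building-block composition (cross-check route).

    A state assignment is accepted iff for some choice of bond orders on
    the four inter-ring bonds, every unit admits a block with matching
    dangling orders: unit i's dangling_2 and unit i+1's dangling_7 share
    the C2(i)-C7(i+1) bond.
    """
    library = derive_block_library(include_three_electron_blocks)
    by_key = {
        (b.state, b.dangling_2, b.dangling_7): True for b in library
    }
    cap = 3 if include_three_electron_blocks else max_unit_oxidation
    names = set()
    for assign in _canonical_assignments(level, cap):
        for orders in itertools.product(("single", "double"), repeat=4):
            ok = all(
                (assign[i], orders[i], orders[(i - 1) % 4]) in by_key
                for i in range(4)
            )
            if ok:
                names.add(TautomerName(assign))
                break
    return frozenset(names)


# ---------------------------------------------------------------------------
# whole-graph enumeration

def _canonical_assignments(level: int, cap: int) -> Iterable[tuple]:
    """Canonical per-unit state assignments of a given total level."""
    seen = set()
    for assign in itertools.product(UNIT_STATES, repeat=4):
        if sum(len(s) for s in assign) != level:
            continue
        if any(len(s) > cap for s in assign):
            continue
        name = canonical_form(TautomerName(assign))
        if name.removed not in seen:
            seen.add(name.removed)
            yield name.removed


def is_closed_shell(name: TautomerName) -> bool:
    """True iff at least one closed-shell valence structure exists."""
    return valence.has_kekule_structure(name)


def enumerate_closed_shell(
    level: int,
    max_unit_oxidation: int = 2,
    include_three_electron_blocks: bool = False,
    with_motifs: bool = True,
) -> TautomerCensus:
    """All distinct closed-shell tautomers at an even oxidation level.

    Reproduces the tautomer censuses of the system: 1 at level 0, 7 at
    level 2 (three single-ring plus four inter-ring), 49 at level 4, 74 at
    level 6, 24 at level 8, and none at levels 10/12 even when
    three-electron blocks are admitted.

    Raises ``ValueError`` for odd levels (open-shell by parity) or levels
    outside [0, 12].
    """
    if not 0 <= level <= 12:
        raise ValueError(f"oxidation level must be in [0, 12], got {level}")
    if level % 2:
        raise ValueError(
            f"level {level} is odd: such species are open-shell by parity"
        )
    cap = 3 if include_three_electron_blocks else max_unit_oxidation
    names = frozenset(
        TautomerName(assign)
        for assign in _canonical_assignments(level, cap)
        if valence.has_kekule_structure(TautomerName(assign))
    )
    counts: dict[str, int] = {}
    if with_motifs:
        for name in names:
            for tag in classify_motifs(name):
                counts[tag] = counts.get(tag, 0) + 1
    return TautomerCensus(level=level, names=names, counts_by_motif=counts)


def enumerate_open_shell(level: int) -> frozenset:
    """All canonical removed-H mappings at a level, closed-shell or not.

    Supports radical/anion site exploration: no valence-feasibility
    constraint and no per-unit cap is applied.
    """
    if not 0 <= level <= 12:
        raise ValueError(f"oxidation level must be in [0, 12], got {level}")
    return frozenset(
        TautomerName(assign) for assign in _canonical_assignments(level, cap=3)
    )


# ---------------------------------------------------------------------------
# motif classification

def _longest_circular_run(flags: list[bool]) -> int:
    if all(flags):
        return len(flags)
    doubled = flags + flags
    best = run = 0
    for f in doubled:
        run = run + 1 if f else 0
        best = max(best, run)
    return min(best, len(flags))


def classify_motifs(name: TautomerName) -> frozenset:
    """Structural motif of a closed-shell tautomer.

    Inferred from which inter-ring bonds can be double in some valence
    structure: a macrocyclic alternating circuit dominates; otherwise two
    consecutive inter-ring doubles mark a system delocalized over three
    units; a single inter-ring double marks a two-unit extended quinonoid;
    with no inter-ring double possible the oxidation is ring-localized,
    the special x,y,x,y pattern of two-electron states (quinone methides
    alternating with o-quinones, as in a16_b56_c16_d56) being tagged
    separately.  Raises ``ValueError`` on open-shell input; the fully
    reduced form carries no tag.
    """
    structures = valence.kekule_structures(name)
    if not structures:
        raise ValueError(f"{name} is open-shell: motifs are undefined")
    if name.level == 0:
        return frozenset()
    if macro := valence.macrocyclic_pi_counts(name):
        assert macro  # non-empty set of pi counts
        return frozenset({"macrocyclic-conjugated"})
    interring = build_skeleton().interring_bonds()
    max_run = 0
    for s in structures:
        flags = [b in s.double_bonds for b in interring]
        max_run = max(max_run, _longest_circular_run(flags))
    if max_run >= 2:
        return frozenset({"three-ring-chain"})
    if max_run == 1:
        return frozenset({"interring-pair"})
    states = name.removed
    if (
        all(len(s) == 2 for s in states)
        and states[0] == states[2]
        and states[1] == states[3]
        and states[0] != states[1]
    ):
        return frozenset({"alternating-localized-quinonoid"})
    return frozenset({"single-ring-localized"})
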