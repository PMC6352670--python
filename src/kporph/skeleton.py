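"""Molecular graph and naming scheme for the Kaxiras porphyrin (KP).

KP is the cyclic tetramer of 5,6-dihydroxyindole (DHI) units joined head to
tail by 2,7'-bonds.  Each unit carries three mobile hydrogens, on N1, O5-H
and O6-H; oxidation by ``n`` electrons removes ``n`` of these hydrogens (and
``n`` electrons), so a species is identified by which hydrogens are missing
on each of the four units.  This module defines:

* the 44-heavy-atom molecular graph (:func:`build_skeleton`),
* the ``aXX_bXX_cXX_dXX`` species naming scheme
  (:func:`parse_name` / :func:`format_name`),
* the cyclic-rotation equivalence used to discard duplicate tautomers
  (:func:`canonical_form`).

The four units are labelled ``a``-``d`` in the order of the 2,7'-coupling,
which is directional (C2 of one unit bonds C7 of the next), so only the
four cyclic rotations — never reflections — are graph automorphisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "UNITS",
    "MOBILE_SITE_LABELS",
    "RING_ATOM_LABELS",
    "MobileSite",
    "TautomerName",
    "PorphyrinGraph",
    "NameParseError",
    "build_skeleton",
    "parse_name",
    "format_name",
    "canonical_form",
    "oxidation_level",
    "rotations",
]

#: Unit labels in 2,7'-coupling order (cyclic: a->b->c->d->a).
UNITS: tuple[str, ...] = ("a", "b", "c", "d")

#: Heteroatom sites that carry a mobile hydrogen in the fully reduced form.
MOBILE_SITE_LABELS: tuple[str, ...] = ("N1", "O5", "O6")

#: Heavy atoms of one DHI unit, in deterministic order.
RING_ATOM_LABELS: tuple[str, ...] = (
    "N1", "C2", "C3", "C3a", "C4", "C5", "C6", "C7", "C7a", "O5", "O6",
)

#: Intra-unit bonds: the nine-membered indole ring plus the two C-O bonds.
_INTRA_UNIT_BONDS: tuple[tuple[str, str], ...] = (
    ("N1", "C2"), ("C2", "C3"), ("C3", "C3a"), ("C3a", "C4"),
    ("C4", "C5"), ("C5", "C6"), ("C6", "C7"), ("C7", "C7a"),
    ("C7a", "N1"), ("C3a", "C7a"), ("C5", "O5"), ("C6", "O6"),
)

#: Digit used for each site in the name string.
_SITE_TO_DIGIT = {"N1": "1", "O5": "5", "O6": "6"}
_DIGIT_TO_SITE = {v: k for k, v in _SITE_TO_DIGIT.items()}

#: Bitmask encoding used to order per-unit states (N1->1, O5->2, O6->4).
_SITE_BIT = {"N1": 1, "O5": 2, "O6": 4}

Atom = tuple[str, str]
Bond = frozenset


class NameParseError(ValueError):
    """Raised when a species name string does not follow the naming scheme."""


@dataclass(frozen=True)
class MobileSite:
    """One of the 12 heteroatom positions that can hold a mobile hydrogen."""

    unit: str
    site: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit label {self.unit!r}")
        if self.site not in MOBILE_SITE_LABELS:
            raise ValueError(f"unknown mobile site {self.site!r}")


@dataclass(frozen=True)
class TautomerName:
    """A KP species: which mobile hydrogens are removed on each unit.

    ``removed`` holds one frozenset per unit, in unit order a..d, each a
    subset of ``{"N1", "O5", "O6"}``.  The string form is the paper-style
    ``aXX_bXX_cXX_dXX`` name, e.g. ``a56_b16_c0_d0``.
    """

    removed: tuple[frozenset, frozenset, frozenset, frozenset]

    def __post_init__(self) -> None:
        if len(self.removed) != 4:
            raise ValueError("a tautomer name needs exactly four unit states")
        for state in self.removed:
            if not frozenset(state) <= frozenset(MOBILE_SITE_LABELS):
                raise ValueError(f"invalid unit state {set(state)!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, set]) -> "TautomerName":
        """Build from a unit-label -> removed-sites mapping."""
        if set(mapping) != set(UNITS):
            raise ValueError(f"units must be exactly {set(UNITS)}, got {set(mapping)}")
        return cls(tuple(frozenset(mapping[u]) for u in UNITS))

    def removed_by_unit(self) -> dict[str, frozenset]:
        return dict(zip(UNITS, self.removed))

    @property
    def level(self) -> int:
        """Oxidation level: total number of removed mobile hydrogens."""
        return sum(len(s) for s in self.removed)

    def rotate(self, k: int = 1) -> "TautomerName":
        """Rotate unit labels k steps along the a->b->c->d->a cycle.

        The state that was on unit ``a`` moves to unit ``b`` for ``k=1``
        (relabelling the same molecule starting from a different unit).
        """
        k %= 4
        return TautomerName(self.removed[-k:] + self.removed[:-k])

    def __str__(self) -> str:
        return format_name(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TautomerName({format_name(self)!r})"

    def __lt__(self, other: "TautomerName") -> bool:
        return _encode(self) < _encode(other)


@dataclass(frozen=True)
class PorphyrinGraph:
    """The 44-heavy-atom molecular graph of the KP macrocycle.

    Atoms are ``(unit, label)`` pairs; bonds are frozensets of two atoms.
    There are 4 x 12 intra-unit bonds plus the four directional inter-ring
    C2(i)-C7(i+1) bonds, 52 in total.
    """

    atoms: tuple[Atom, ...]
    bonds: frozenset
    mobile_sites: tuple[MobileSite, ...]

    def neighbors(self, atom: Atom) -> tuple[Atom, ...]:
        return self._adjacency[atom]

    @property
    def _adjacency(self) -> dict[Atom, tuple[Atom, ...]]:
        adj = self.__dict__.get("_adj_cache")
        if adj is None:
            adj = {a: [] for a in self.atoms}
            for bond in self.bonds:
                x, y = tuple(bond)
                adj[x].append(y)
                adj[y].append(x)
            adj = {a: tuple(sorted(ns)) for a, ns in adj.items()}
            object.__setattr__(self, "_adj_cache", adj)
        return adj

    def interring_bonds(self) -> tuple[Bond, ...]:
        """The four C2(i)-C7(i+1) bonds, in unit order of the C2 end."""
        out = []
        for i, u in enumerate(UNITS):
            v = UNITS[(i + 1) % 4]
            out.append(frozenset({(u, "C2"), (v, "C7")}))
        return tuple(out)


def build_skeleton() -> PorphyrinGraph:
    """Construct the KP molecular graph with deterministic atom ordering."""
    atoms = tuple((u, label) for u in UNITS for label in RING_ATOM_LABELS)
    bonds = set()
    for u in UNITS:
        for x, y in _INTRA_UNIT_BONDS:
            bonds.add(frozenset({(u, x), (u, y)}))
    for i, u in enumerate(UNITS):
        v = UNITS[(i + 1) % 4]
        bonds.add(frozenset({(u, "C2"), (v, "C7")}))
    sites = tuple(MobileSite(u, s) for u in UNITS for s in MOBILE_SITE_LABELS)
    return PorphyrinGraph(atoms=atoms, bonds=frozenset(bonds), mobile_sites=sites)


def parse_name(text: str) -> TautomerName:
    """Parse an ``aXX_bXX_cXX_dXX`` name string.

    Digits 1, 5, 6 denote removed hydrogens on N1, O5, O6; ``0`` denotes
    none.  Raises :class:`NameParseError` naming the offending token for
    wrong unit order, repeated digits, or digits outside {0,1,5,6}.
    """
    tokens = text.strip().split("_")
    if len(tokens) != 4:
        raise NameParseError(f"expected four underscore-separated tokens in {text!r}")
    states = []
    for expected_unit, token in zip(UNITS, tokens):
        if not token or token[0] != expected_unit:
            raise NameParseError(
                f"token {token!r}: expected unit {expected_unit!r} at this position"
            )
        digits = token[1:]
        if not digits:
            raise NameParseError(f"token {token!r}: missing digits")
        if digits == "0":
            states.append(frozenset())
            continue
        seen: set[str] = set()
        for ch in digits:
            if ch not in _DIGIT_TO_SITE:
                raise NameParseError(f"token {token!r}: digit {ch!r} not in {{0,1,5,6}}")
            if ch in seen:
                raise NameParseError(f"token {token!r}: repeated digit {ch!r}")
            seen.add(ch)
        states.append(frozenset(_DIGIT_TO_SITE[ch] for ch in seen))
    return TautomerName(tuple(states))


def format_name(name: TautomerName) -> str:
    """Render the paper-style name string (digits ascending, 0 for empty)."""
    parts = []
    for unit, state in zip(UNITS, name.removed):
        digits = "".join(sorted(_SITE_TO_DIGIT[s] for s in state)) or "0"
        parts.append(unit + digits)
    return "_".join(parts)


def _encode(name: TautomerName) -> tuple[int, int, int, int]:
    """Per-unit bitmask 4-tuple used for canonical ordering."""
    return tuple(sum(_SITE_BIT[s] for s in state) for state in name.removed)


def rotations(name: TautomerName) -> Iterator[TautomerName]:
    """The orbit of a name under the four cyclic unit-label rotations."""
    for k in range(4):
        yield name.rotate(k)


def canonical_form(name: TautomerName) -> TautomerName:
    """Orbit representative under cyclic rotation of the unit labels.

    The representative is the rotation whose per-unit bitmask 4-tuple
    (N1->1, O5->2, O6->4) is lexicographically smallest.  Two names denote
    the same molecule iff their canonical forms are equal.  Idempotent.
    """
    return min(rotations(name), key=_encode)


def oxidation_level(name: TautomerName) -> int:
    """Number of removed mobile hydrogens; KP-ne species have level n."""
    return name.level
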