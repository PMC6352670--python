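"""Record file I/O and SDF structure export.

Species records travel as a single versioned JSON document with explicit
units on every energy field (hartree, eV, cm⁻¹ — see
:class:`~kporph.thermo.SpeciesRecord`).  Unknown fields are preserved on
round-trip, and writing is normalized (sorted keys, fixed indentation) so
that write∘read is the identity on normalized files.

Structure export writes an SDF V2000 connection table for the 44-heavy-atom
macrocycle, with bond orders taken from the lexicographically first Kekulé
structure and a deterministic schematic radial 2-D layout (the real
geometries are not modelled; the comment line flags this).  Standard
implicit-valence rules then imply exactly the right hydrogen count at every
atom: one H on C3/C4, one on each heteroatom that kept its mobile hydrogen,
none elsewhere.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Union

from pydantic import BaseModel, ConfigDict, ValidationError

from .skeleton import (
    RING_ATOM_LABELS,
    TautomerName,
    UNITS,
    build_skeleton,
    format_name,
)
from .thermo import SpeciesRecord
from .valence import kekule_structures

__all__ = ["FORMAT_VERSION", "RecordFile", "read_records", "write_records", "export_sdf"]

FORMAT_VERSION = "kporph-records-1"

_PathLike = Union[str, Path]


class RecordFile(BaseModel):
    """A versioned collection of species records."""

    model_config = ConfigDict(extra="allow")

    format_version: str = FORMAT_VERSION
    records: list[SpeciesRecord]


def write_records(record_file: RecordFile, path: _PathLike) -> None:
    """Write records as normalized JSON (sorted keys, 2-space indent)."""
    payload = record_file.model_dump(mode="json")
    text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    Path(path).write_text(text)


def read_records(path: _PathLike) -> RecordFile:
    """Read and validate a record file.

    Schema violations are reported with the record index and field name;
    an unrecognized format version is rejected up front.
    """
    raw = json.loads(Path(path).read_text())
    version = raw.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"unrecognized format_version {version!r} (expected {FORMAT_VERSION!r})"
        )
    try:
        return RecordFile.model_validate(raw)
    except ValidationError as err:
        details = []
        for item in err.errors():
            loc = item["loc"]
            if loc and loc[0] == "records" and len(loc) > 1:
                details.append(
                    f"record {loc[1]}, field {'.'.join(str(p) for p in loc[2:]) or '<root>'}: "
                    f"{item['msg']}"
                )
            else:  # pragma: no cover - top-level schema errors
                details.append(f"{'.'.join(str(p) for p in loc)}: {item['msg']}")
        raise ValueError("invalid record file: " + "; ".join(details)) from err


# ---------------------------------------------------------------------------
# SDF export

#: Schematic local 2-D layout of one unit (x outward, y along the ring).
_UNIT_LAYOUT = {
    "C2": (0.0, 1.0),
    "N1": (1.0, 1.3),
    "C3": (0.4, 2.0),
    "C3a": (1.4, 2.2),
    "C7a": (1.8, 1.2),
    "C4": (2.0, 3.0),
    "C5": (3.0, 2.9),
    "C6": (3.3, 1.9),
    "C7": (2.8, 1.0),
    "O5": (3.7, 3.7),
    "O6": (4.3, 1.8),
}

_UNIT_RADIUS = 3.0  # ring-center offset from the macrocycle center


def export_sdf(name: TautomerName, path: _PathLike) -> None:
    """Write an SDF V2000 file for a closed-shell tautomer.

    44 heavy atoms, 52 bonds; double bonds from the lexicographically
    first Kekulé structure; units placed on a circle (schematic layout).
    Raises ``ValueError`` for open-shell names.
    """
    structures = kekule_structures(name)
    if not structures:
        raise ValueError(f"{format_name(name)} is open-shell: no Kekulé structure")
    double_bonds = structures[0].double_bonds

    graph = build_skeleton()
    atoms = list(graph.atoms)
    index = {atom: i + 1 for i, atom in enumerate(atoms)}

    lines = [
        format_name(name),
        "  kporph",
        "schematic radial 2D layout; bond orders from first Kekule structure",
        f"{len(atoms):3d}{len(graph.bonds):3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for unit, label in atoms:
        angle = math.radians(90.0 * UNITS.index(unit))
        lx, ly = _UNIT_LAYOUT[label]
        px, py = lx + _UNIT_RADIUS, ly
        x = px * math.cos(angle) - py * math.sin(angle)
        y = px * math.sin(angle) + py * math.cos(angle)
        element = label[0]
        lines.append(
            f"{x:10.4f}{y:10.4f}{0.0:10.4f} {element:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for bond in sorted(tuple(sorted(index[a] for a in b)) for b in graph.bonds):
        i, j = bond
        atom_i = atoms[i - 1]
        atom_j = atoms[j - 1]
        order = 2 if frozenset({atom_i, atom_j}) in double_bonds else 1
        lines.append(f"{i:3d}{j:3d}{order:3d}  0")
    lines.append("M  END")
    lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + "\n")


def _atom_order_check() -> None:  # pragma: no cover - import-time sanity
    assert len(RING_ATOM_LABELS) == 11


_atom_order_check()
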