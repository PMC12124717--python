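"""Atom typing: base labels for the organic scaffold and unique labels for
every metal-coordinating atom.

The unique-labeling step gives each atom that directly coordinates a metal its
own atom type (e.g. the six nitrogens of an octahedral tris-bidentate complex
become N1..N6), so every metal-involving bond and angle resolves to its own
parameter entry instead of collapsing onto one shared key.  Coordinating atoms
of the first metal are suffixed with digits, of the second with uppercase
letters, and later metals continue through further deterministic alphabets;
label collisions advance the alphabet.

Base types for the rest of the molecule use a simple element+coordination
heuristic and can be overridden wholesale with a per-atom list produced by an
external typing tool.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from enum import Enum

from .qm_io import MolecularGeometry
from .topology import Topology

MAX_LABEL_LEN = 4


class TypeProvenance(str, Enum):
    BASE = "base"
    ULS = "uls"
    METAL = "metal"


@dataclass
class AtomTypeAssignment:
    """Per-atom type labels plus bookkeeping of which atoms carry unique
    metal-coordination labels."""

    types: list[str]
    uls_atoms: set[int] = field(default_factory=set)
    provenance: list[TypeProvenance] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.types:
            if t and len(t) > MAX_LABEL_LEN:
                raise ValueError(f"atom type {t!r} exceeds {MAX_LABEL_LEN} chars")
        if not self.provenance:
            self.provenance = [TypeProvenance.BASE] * len(self.types)

    def type_of(self, i: int) -> str:
        return self.types[i]


def assign_base_types(geometry: MolecularGeometry,
                      topology: Topology,
                      override: list[str] | None = None,
                      ) -> AtomTypeAssignment:
    """Assign base types to every atom.

    The heuristic label is the lower-cased element symbol suffixed with the
    coordination number (``c3`` for a three-neighbor carbon).  Metal atoms
    carry their element symbol verbatim.  A full-length ``override`` list
    replaces the heuristic labels for non-metal atoms.
    """
    n = geometry.n_atoms
    if override is not None and len(override) != n:
        raise ValueError(
            f"type override has {len(override)} entries for {n} atoms"
        )
    types: list[str] = []
    prov: list[TypeProvenance] = []
    for i, el in enumerate(geometry.elements):
        if i in topology.metal_indices:
            types.append(el)
            prov.append(TypeProvenance.METAL)
        elif override is not None:
            if len(override[i]) > MAX_LABEL_LEN:
                raise ValueError(
                    f"override type {override[i]!r} exceeds {MAX_LABEL_LEN} chars"
                )
            types.append(override[i])
            prov.append(TypeProvenance.BASE)
        else:
            types.append(f"{el.lower()}{len(topology.neighbors(i))}")
            prov.append(TypeProvenance.BASE)
    return AtomTypeAssignment(types=types, provenance=prov)


def _suffix_alphabets() -> list[str]:
    """Per-metal suffix alphabets: digits, uppercase, lowercase, then
    two-character digit+letter combinations for further metals."""
    alphabets = [
        "123456789",
        string.ascii_uppercase,
        string.ascii_lowercase,
    ]
    for d in string.digits[1:]:
        alphabets.append("".join(d + c for c in string.ascii_uppercase))
    return alphabets


def apply_uls(assignment: AtomTypeAssignment,
              geometry: MolecularGeometry,
              topology: Topology) -> AtomTypeAssignment:
    """Relabel every metal-coordinating atom with a globally unique type.

    Metals are processed in index order; each metal's coordinating atoms (in
    index order) draw suffixes from that metal's alphabet.  An atom bridging
    two metals keeps the label from the first metal that reaches it.  Labels
    already in use advance the alphabet until free.
    """
    used = set(assignment.types)
    alphabets = _suffix_alphabets()
    n_coord = sum(len(v) for v in topology.coordination.values())
    if n_coord > 99:
        raise ValueError(
            f"{n_coord} coordinating atoms exceed the label alphabet"
        )
    for metal_rank, metal in enumerate(sorted(topology.coordination)):
        if metal_rank >= len(alphabets):
            raise ValueError("more metals than suffix alphabets available")
        alphabet = iter(alphabets[metal_rank])
        for atom in topology.coordination[metal]:
            if atom in assignment.uls_atoms or atom in topology.metal_indices:
                continue
            base = geometry.elements[atom]
            label = None
            for suffix in alphabet:
                candidate = f"{base}{suffix}"
                if len(candidate) <= MAX_LABEL_LEN and candidate not in used:
                    label = candidate
                    break
            if label is None:
                raise ValueError(
                    f"suffix alphabet exhausted for metal {metal} "
                    f"(atom {atom}, element {base})"
                )
            assignment.types[atom] = label
            assignment.provenance[atom] = TypeProvenance.ULS
            assignment.uls_atoms.add(atom)
            used.add(label)
    return assignment


def assign_types(geometry: MolecularGeometry,
                 topology: Topology,
                 override: list[str] | None = None,
                 uls: bool = True) -> AtomTypeAssignment:
    """Base typing followed (by default) by unique labeling of coordinating
    atoms."""
    assignment = assign_base_types(geometry, topology, override)
    if uls:
        apply_uls(assignment, geometry, topology)
    return assignment


def parameter_key(term: tuple[int, ...],
                  assignment: AtomTypeAssignment) -> tuple[str, ...]:
    """Canonical (reverse-symmetric) type-tuple key for a bond, angle, or
    dihedral term: ``key(A, B, C) == key(C, B, A)``."""
    labels = tuple(assignment.types[i] for i in term)
    return min(labels, labels[::-1])
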