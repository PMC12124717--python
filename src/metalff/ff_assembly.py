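"""Hybrid parameter assembly: Seminario-derived metal terms merged with
transferable-database parameters, UFF-derived metal Lennard-Jones entries,
masses, and charges.

The merge policy is the hybrid split of the bonded-model workflow:

* every bond/angle that involves a metal atom takes its Seminario value;
* non-metal terms are looked up in the transferable database (frcmod/dat
  syntax); a miss falls back to the Seminario value and is flagged as missing
  in the database;
* metal-involving dihedrals get a single explicit zero-barrier term (the
  bonded model neglects metal torsions, but MD engines want complete records);
* metal Lennard-Jones terms come from the embedded UFF subset with the vdW
  distance halved (Amber NONBON carries R_min/2), ε unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from ._elements import UFF_LJ, atomic_mass, normalize_symbol
from .atom_typing import AtomTypeAssignment, parameter_key
from .qm_io import ChargeSet
from .seminario import AngleParameter, BondParameter
from .topology import Topology

logger = logging.getLogger(__name__)

AMBER_SCEE = 1.2
AMBER_SCNB = 2.0


class Provenance(str, Enum):
    SEMINARIO = "seminario"
    DATABASE = "database"
    UFF = "uff"
    ZEROED = "zeroed"


@dataclass
class BondEntry:
    k: float      # kcal/mol/Å²
    r_eq: float   # Å
    provenance: Provenance


@dataclass
class AngleEntry:
    k_theta: float  # kcal/(mol rad²)
    theta_eq: float  # degrees
    provenance: Provenance


@dataclass
class DihedralTerm:
    idivf: int
    barrier: float  # PK = V_n/2, kcal/mol
    phase: float    # degrees
    periodicity: int


@dataclass
class DihedralEntry:
    terms: list[DihedralTerm]
    provenance: Provenance


@dataclass
class LennardJonesEntry:
    type_label: str
    r_min_half: float  # Å
    epsilon: float     # kcal/mol
    source: str = ""

    def __post_init__(self) -> None:
        if self.r_min_half <= 0:
            raise ValueError("r_min_half must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class ForceFieldParameterSet:
    """Complete assembled parameter set keyed by canonical type tuples."""

    masses: dict[str, float] = field(default_factory=dict)
    bonds: dict[tuple[str, str], BondEntry] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleEntry] = field(default_factory=dict)
    dihedrals: dict[tuple[str, str, str, str], DihedralEntry] = field(
        default_factory=dict)
    impropers: dict[tuple[str, str, str, str], DihedralEntry] = field(
        default_factory=dict)
    lj: dict[str, LennardJonesEntry] = field(default_factory=dict)
    charges: ChargeSet | None = None
    missing_in_database: list[tuple[str, ...]] = field(default_factory=list)

    def provenance_counts(self) -> dict[str, int]:
        counts = {p.value: 0 for p in Provenance}
        for entry in list(self.bonds.values()) + list(self.angles.values()):
            counts[entry.provenance.value] += 1
        for entry in self.dihedrals.values():
            counts[entry.provenance.value] += 1
        for entry in self.lj.values():
            if entry.source.startswith("UFF"):
                counts[Provenance.UFF.value] += 1
            elif entry.source == "database":
                counts[Provenance.DATABASE.value] += 1
            else:
                counts.setdefault("default_lj", 0)
                counts["default_lj"] = counts.get("default_lj", 0) + 1
        return counts


class DatabaseParseError(ValueError):
    pass


class AssemblyError(ValueError):
    pass


def _canonical(labels: tuple[str, ...]) -> tuple[str, ...]:
    return min(labels, labels[::-1])


@dataclass
class ParameterDatabase:
    """Transferable-parameter lookup indexed by canonical type tuple."""

    masses: dict[str, float] = field(default_factory=dict)
    bonds: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict)
    angles: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=dict)
    dihedrals: dict[tuple[str, str, str, str], list[DihedralTerm]] = field(
        default_factory=dict)
    lj: dict[str, tuple[float, float]] = field(default_factory=dict)

    def lookup_bond(self, t1: str, t2: str):
        return self.bonds.get(_canonical((t1, t2)))

    def lookup_angle(self, t1: str, t2: str, t3: str):
        return self.angles.get(_canonical((t1, t2, t3)))

    def lookup_dihedral(self, t1: str, t2: str, t3: str, t4: str):
        exact = self.dihedrals.get(_canonical((t1, t2, t3, t4)))
        if exact is not None:
            return exact
        return self.dihedrals.get(_canonical(("X", t2, t3, "X")))


_TYPES_RE = re.compile(r"^\s*((?:[A-Za-z0-9*+]{1,4}\s*-\s*)+[A-Za-z0-9*+]{1,4})(\s+.*)$")

_SECTION_KEYS = ("MASS", "BOND", "ANGL", "DIHE", "IMPR", "NONB", "HBON")


def _split_types(spec: str) -> tuple[str, ...]:
    return tuple(t.strip() for t in spec.split("-"))


def load_parameter_database(path_or_text: str | Path,
                            include_fallback: bool = False,
                            ) -> ParameterDatabase:
    """Parse an Amber frcmod-style parameter file into an indexed lookup.

    ``include_fallback`` merges a small embedded table of common organic
    types underneath the file's own entries.
    """
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
        name = str(path_or_text)
    else:
        text = str(path_or_text)
        name = "<text>"
    db = default_database() if include_fallback else ParameterDatabase()
    section = None
    for lineno, ln in enumerate(text.splitlines(), 1):
        stripped = ln.strip()
        if lineno == 1 and not stripped.upper().startswith(_SECTION_KEYS):
            continue  # title line
        if not stripped:
            section = None if section == "NONB" else section
            continue
        upper = stripped.upper()
        matched = next((k for k in _SECTION_KEYS if upper.startswith(k)), None)
        if matched and len(stripped.split()[0]) <= 8 and not _TYPES_RE.match(ln):
            section = matched
            continue
        if section is None:
            continue
        try:
            _parse_db_line(db, section, ln)
        except (ValueError, IndexError) as exc:
            raise DatabaseParseError(
                f"{name}: line {lineno} in section {section}: {exc}"
            ) from exc
    return db


def _parse_db_line(db: ParameterDatabase, section: str, ln: str) -> None:
    if section == "MASS":
        parts = ln.split()
        db.masses[parts[0]] = float(parts[1])
        return
    if section == "NONB":
        parts = ln.split()
        db.lj[parts[0]] = (float(parts[1]), float(parts[2]))
        return
    m = _TYPES_RE.match(ln)
    if m is None:
        raise ValueError(f"cannot parse type field in {ln!r}")
    types = _split_types(m.group(1))
    fields = m.group(2).split()
    if section == "BOND":
        if len(types) != 2:
            raise ValueError("BOND line needs two types")
        db.bonds[_canonical(types)] = (float(fields[0]), float(fields[1]))
    elif section == "ANGL":
        if len(types) != 3:
            raise ValueError("ANGLE line needs three types")
        db.angles[_canonical(types)] = (float(fields[0]), float(fields[1]))
    elif section == "DIHE":
        if len(types) != 4:
            raise ValueError("DIHE line needs four types")
        term = DihedralTerm(idivf=int(float(fields[0])),
                            barrier=float(fields[1]),
                            phase=float(fields[2]),
                            periodicity=abs(int(float(fields[3]))))
        key = _canonical(types)
        db.dihedrals.setdefault(key, []).append(term)
    elif section == "IMPR":
        pass  # impropers are carried through unmodified when present
    elif section == "HBON":
        pass


_FALLBACK_FRCMOD = """embedded fallback: common GAFF-style organic types
MASS
ca 12.010
c3 12.010
ha 1.008
hc 1.008
n3 14.010
os 15.999
oh 15.999
ho 1.008

BOND
ca-ca  478.40  1.387
ca-ha  344.30  1.087
c3-c3  303.10  1.535
c3-hc  337.30  1.092
c3-n3  320.60  1.470
c3-os  301.50  1.439
oh-ho  369.60  0.974

ANGLE
ca-ca-ca  67.20  119.97
ca-ca-ha  48.50  120.01
c3-c3-c3  63.21  110.63
c3-c3-hc  46.37  110.05
hc-c3-hc  39.43  108.35

DIHE
X -ca-ca-X    4  14.500  180.0  2
X -c3-c3-X    9   1.400    0.0  3

IMPROPER

NONBON
  ca  1.9080  0.0860
  c3  1.9080  0.1094
  ha  1.4590  0.0150
  hc  1.4870  0.0157
  n3  1.8240  0.1700
  os  1.6837  0.1700
  oh  1.7210  0.2104
  ho  0.3000  0.0000
"""


def default_database() -> ParameterDatabase:
    """Small embedded table of common organic types (GAFF-style values)."""
    return load_parameter_database(_FALLBACK_FRCMOD)


def metal_lj(element: str) -> LennardJonesEntry:
    """UFF-derived Lennard-Jones entry for a metal element.

    The UFF vdW distance is halved (the Amber NONBON column is R_min/2);
    the well depth is taken unchanged.
    """
    sym = normalize_symbol(element)
    if sym not in UFF_LJ:
        raise KeyError(
            f"element {element!r} not in the embedded UFF subset; supply a "
            "manual NONBON entry"
        )
    x, d = UFF_LJ[sym]
    return LennardJonesEntry(type_label=sym, r_min_half=x / 2.0, epsilon=d,
                             source="UFF (R halved)")


ZERO_DIHEDRAL = DihedralTerm(idivf=1, barrier=0.0, phase=0.0, periodicity=1)


def assemble(topology: Topology,
             assignment: AtomTypeAssignment,
             seminario_bonds: list[BondParameter],
             seminario_angles: list[AngleParameter],
             database: ParameterDatabase | None,
             charges: ChargeSet | None = None,
             elements: list[str] | None = None,
             ) -> ForceFieldParameterSet:
    """Merge all parameter sources into one complete set.

    Every topology bond/angle/dihedral key resolves to exactly one entry;
    an unresolvable term raises :class:`AssemblyError` listing the keys.
    """
    db = database or ParameterDatabase()
    ffp = ForceFieldParameterSet(charges=charges)
    sem_bond = {tuple(sorted(p.atoms)): p for p in seminario_bonds}
    sem_angle = {p.atoms: p for p in seminario_angles}
    metals = topology.metal_indices
    unresolved: list[tuple[str, ...]] = []

    for i, j in sorted(topology.bonds):
        key = parameter_key((i, j), assignment)
        sem = sem_bond.get((min(i, j), max(i, j)))
        if {i, j} & metals:
            if sem is None:
                unresolved.append(key)
                continue
            ffp.bonds[key] = BondEntry(sem.k_out, sem.r_eq, Provenance.SEMINARIO)
            continue
        hit = db.lookup_bond(*key)
        if hit is not None:
            ffp.bonds.setdefault(key, BondEntry(hit[0], hit[1],
                                                Provenance.DATABASE))
        elif sem is not None:
            if key not in ffp.bonds:
                ffp.bonds[key] = BondEntry(sem.k_out, sem.r_eq,
                                           Provenance.SEMINARIO)
                ffp.missing_in_database.append(key)
                logger.info("bond %s missing in database; Seminario fallback",
                            "-".join(key))
        else:
            unresolved.append(key)

    for a, b, c in topology.angles:
        key = parameter_key((a, b, c), assignment)
        sem = sem_angle.get((a, b, c))
        if {a, b, c} & metals:
            if sem is None:
                unresolved.append(key)
                continue
            ffp.angles[key] = AngleEntry(sem.k_theta_out, sem.theta_eq,
                                         Provenance.SEMINARIO)
            continue
        hit = db.lookup_angle(*key)
        if hit is not None:
            ffp.angles.setdefault(key, AngleEntry(hit[0], hit[1],
                                                  Provenance.DATABASE))
        elif sem is not None:
            if key not in ffp.angles:
                ffp.angles[key] = AngleEntry(sem.k_theta_out, sem.theta_eq,
                                             Provenance.SEMINARIO)
                ffp.missing_in_database.append(key)
                logger.info("angle %s missing in database; Seminario fallback",
                            "-".join(key))
        else:
            unresolved.append(key)

    for a, b, c, d in topology.dihedrals:
        key = parameter_key((a, b, c, d), assignment)
        if key in ffp.dihedrals:
            continue
        if {a, b, c, d} & metals:
            ffp.dihedrals[key] = DihedralEntry([ZERO_DIHEDRAL],
                                               Provenance.ZEROED)
            continue
        hit = db.lookup_dihedral(*key)
        if hit is not None:
            ffp.dihedrals[key] = DihedralEntry(list(hit), Provenance.DATABASE)
        else:
            ffp.dihedrals[key] = DihedralEntry([ZERO_DIHEDRAL],
                                               Provenance.ZEROED)
            ffp.missing_in_database.append(key)

    if unresolved:
        raise AssemblyError(
            "no parameter resolvable for terms: "
            + ", ".join("-".join(k) for k in unresolved)
        )

    if elements is not None:
        type_elem: dict[str, str] = {}
        for idx, label in enumerate(assignment.types):
            type_elem.setdefault(label, elements[idx])
        for label, el in sorted(type_elem.items()):
            ffp.masses[label] = db.masses.get(label, atomic_mass(el))
            if label in db.lj:
                r, eps = db.lj[label]
                ffp.lj[label] = LennardJonesEntry(label, r, eps,
                                                  source="database")
            elif idx_is_metal_type(label, assignment, topology):
                ffp.lj[label] = metal_lj(el)
            else:
                # unknown organic type: benign placeholder the user can edit
                ffp.lj[label] = LennardJonesEntry(label, 1.5, 0.05,
                                                  source="default")
    return ffp


def idx_is_metal_type(label: str, assignment: AtomTypeAssignment,
                      topology: Topology) -> bool:
    return any(assignment.types[m] == label for m in topology.metal_indices)
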