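"""Emit Amber-ecosystem files: frcmod parameter modifications, TRIPOS mol2,
PDB (HETATM) coordinates, and a minimal leap library entry.

All writers are deterministic: identical inputs give byte-identical text.
frcmod records order metal-involving terms first, then lexicographically, and
print at the conventional precisions (bond k to 3 decimals, lengths to 4,
angles to 2/3) so that re-parsing reproduces every value exactly at the
printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._elements import ATOMIC_NUMBERS
from .atom_typing import AtomTypeAssignment, MAX_LABEL_LEN
from .ff_assembly import (AMBER_SCEE, AMBER_SCNB, ForceFieldParameterSet,
                          Provenance)
from .qm_io import ChargeSet, MolecularGeometry
from .topology import Topology

DEFAULT_RESIDUE = "LIG"


@dataclass
class OutputBundle:
    frcmod: str
    mol2: str
    pdb: str
    lib: str | None = None
    residue: str = DEFAULT_RESIDUE
    manifest: list[str] = field(default_factory=list)


def _fmt_type(t: str) -> str:
    if len(t) > MAX_LABEL_LEN:
        raise ValueError(f"type label {t!r} exceeds {MAX_LABEL_LEN} characters")
    return f"{t:<2s}"


def _metal_first(key: tuple[str, ...], metal_types: set[str]):
    return (0 if set(key) & metal_types else 1, key)


def write_frcmod(params: ForceFieldParameterSet,
                 title: str = "metalff parameters "
                              "(harmonic constants doubled: E = K(x-x0)^2)",
                 metal_types: set[str] | None = None) -> str:
    """Render the parameter set as frcmod text with MASS/BOND/ANGLE/DIHE/
    IMPROPER/NONBON sections.

    Raises when the set holds no bonded terms at all (nothing to write).
    """
    if not (params.bonds or params.angles or params.dihedrals):
        raise ValueError("parameter set is empty: nothing to write")
    metal_types = metal_types or {
        label for label, entry in params.lj.items()
        if entry.source.startswith("UFF")
    }
    out: list[str] = [title]
    out.append("MASS")
    for label in sorted(params.masses,
                        key=lambda t: (0 if t in metal_types else 1, t)):
        out.append(f"{_fmt_type(label)} {params.masses[label]:10.3f}")
    out.append("")
    out.append("BOND")
    for key in sorted(params.bonds, key=lambda k: _metal_first(k, metal_types)):
        e = params.bonds[key]
        out.append(f"{_fmt_type(key[0])}-{_fmt_type(key[1])}  "
                   f"{e.k:10.3f}  {e.r_eq:8.4f}")
    out.append("")
    out.append("ANGLE")
    for key in sorted(params.angles, key=lambda k: _metal_first(k, metal_types)):
        e = params.angles[key]
        out.append(f"{_fmt_type(key[0])}-{_fmt_type(key[1])}-"
                   f"{_fmt_type(key[2])}  {e.k_theta:10.3f}  {e.theta_eq:9.3f}")
    out.append("")
    out.append("DIHE")
    for key in sorted(params.dihedrals,
                      key=lambda k: _metal_first(k, metal_types)):
        entry = params.dihedrals[key]
        for i, term in enumerate(entry.terms):
            # negative periodicity marks continuation lines in Amber
            pn = term.periodicity if i == len(entry.terms) - 1 else -term.periodicity
            out.append(
                f"{_fmt_type(key[0])}-{_fmt_type(key[1])}-"
                f"{_fmt_type(key[2])}-{_fmt_type(key[3])}  "
                f"{term.idivf:3d}  {term.barrier:9.3f}  {term.phase:8.1f}  "
                f"{pn:4d}    SCEE={AMBER_SCEE} SCNB={AMBER_SCNB}"
            )
    out.append("")
    out.append("IMPROPER")
    for key in sorted(params.impropers,
                      key=lambda k: _metal_first(k, metal_types)):
        entry = params.impropers[key]
        for term in entry.terms:
            out.append(
                f"{_fmt_type(key[0])}-{_fmt_type(key[1])}-"
                f"{_fmt_type(key[2])}-{_fmt_type(key[3])}  "
                f"{term.barrier:9.3f}  {term.phase:8.1f}  "
                f"{term.periodicity:4d}"
            )
    out.append("")
    out.append("NONBON")
    for label in sorted(params.lj,
                        key=lambda t: (0 if t in metal_types else 1, t)):
        e = params.lj[label]
        out.append(f"  {_fmt_type(label)}  {e.r_min_half:8.4f}  "
                   f"{e.epsilon:8.4f}")
    out.append("")
    return "\n".join(out) + "\n"


def write_mol2(geometry: MolecularGeometry,
               topology: Topology,
               assignment: AtomTypeAssignment,
               charges: ChargeSet | None = None,
               residue: str = DEFAULT_RESIDUE,
               title: str = "metalff") -> str:
    """Render a TRIPOS mol2 file with the perceived bond set, type labels,
    and charges."""
    n = geometry.n_atoms
    q = charges.charges if charges is not None else np.zeros(n)
    if len(q) != n:
        raise ValueError(f"{len(q)} charges for {n} atoms")
    bonds = sorted(topology.bonds)
    lines = ["@<TRIPOS>MOLECULE", title,
             f"{n:5d} {len(bonds):5d} {1:5d} {0:5d} {0:5d}",
             "SMALL", "USER_CHARGES", "", "@<TRIPOS>ATOM"]
    for i in range(n):
        el = geometry.elements[i]
        x, y, z = geometry.coordinates[i]
        lines.append(
            f"{i + 1:7d} {el + str(i + 1):<8s} {x:10.4f} {y:10.4f} "
            f"{z:10.4f} {assignment.types[i]:<6s} {1:5d} {residue:<4s} "
            f"{q[i]:10.6f}"
        )
    lines.append("@<TRIPOS>BOND")
    for b, (i, j) in enumerate(bonds, 1):
        lines.append(f"{b:6d} {i + 1:5d} {j + 1:5d} 1")
    return "\n".join(lines) + "\n"


def write_pdb(geometry: MolecularGeometry,
              residue: str = DEFAULT_RESIDUE) -> str:
    """Render single-residue HETATM records (PDB v3.3 columns; element
    right-justified in columns 77–78)."""
    if geometry.n_atoms > 99999:
        raise ValueError("too many atoms for PDB serial numbers")
    lines = []
    for i in range(geometry.n_atoms):
        el = geometry.elements[i]
        x, y, z = geometry.coordinates[i]
        name = (el + str(i + 1))[:4]
        lines.append(
            f"HETATM{i + 1:5d} {name:<4s} {residue:<3s} A{1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{el.upper():>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_lib(geometry: MolecularGeometry,
              topology: Topology,
              assignment: AtomTypeAssignment,
              charges: ChargeSet | None = None,
              residue: str = DEFAULT_RESIDUE) -> str:
    """Minimal leap library entry: atoms table plus connectivity."""
    n = geometry.n_atoms
    q = charges.charges if charges is not None else np.zeros(n)
    lines = ["!!index array str", f' "{residue}"',
             f'!entry.{residue}.unit.atoms table  str name  str type  '
             "int typex  int resx  int flags  int seq  int elmnt  dbl chg"]
    for i in range(n):
        el = geometry.elements[i]
        lines.append(
            f' "{el}{i + 1}" "{assignment.types[i]}" 0 1 131072 {i + 1} '
            f"{ATOMIC_NUMBERS[el]} {q[i]:.6f}"
        )
    lines.append(f"!entry.{residue}.unit.connectivity table  int atom1x  "
                 "int atom2x  int flags")
    for i, j in sorted(topology.bonds):
        lines.append(f" {i + 1} {j + 1} 1")
    return "\n".join(lines) + "\n"


def write_bundle(geometry: MolecularGeometry,
                 topology: Topology,
                 assignment: AtomTypeAssignment,
                 params: ForceFieldParameterSet,
                 charges: ChargeSet | None = None,
                 residue: str = DEFAULT_RESIDUE,
                 emit_lib: bool = False) -> OutputBundle:
    metal_types = {assignment.types[m] for m in topology.metal_indices}
    bundle = OutputBundle(
        frcmod=write_frcmod(params, metal_types=metal_types),
        mol2=write_mol2(geometry, topology, assignment, charges, residue),
        pdb=write_pdb(geometry, residue),
        lib=write_lib(geometry, topology, assignment, charges, residue)
        if emit_lib else None,
        residue=residue,
    )
    return bundle
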