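"""Connectivity perception and topology enumeration.

Bonds are perceived from interatomic distances against summed covalent radii;
angles and proper dihedrals are expanded combinatorially from the bond graph.
Metal centers, their coordination spheres (directly bonded neighbors), and
groups of linked metals are identified here.  Multimetallic cores with more
than four linked metals are rejected, matching the tool's validated domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from ._elements import covalent_radius, is_metal
from .qm_io import MolecularGeometry

#: two atoms closer than this (Å) are considered overlapping — input error
MIN_CONTACT = 0.4

#: default multiplier on summed covalent radii for the bond criterion
DEFAULT_TOLERANCE_FACTOR = 1.25

#: largest allowed connected group of linked metals
MAX_LINKED_METALS = 4


@dataclass
class Topology:
    """Bond graph plus derived valence terms and metal bookkeeping.

    ``bonds`` holds unordered index pairs stored ``(i, j)`` with ``i < j``;
    ``angles`` are ordered triples ``(A, B, C)`` with the vertex ``B`` in the
    middle; ``dihedrals`` are ordered quadruples along a bonded path.
    ``coordination`` maps each metal index to the sorted list of directly
    bonded (coordinating) atom indices.
    """

    n_atoms: int
    bonds: set[tuple[int, int]] = field(default_factory=set)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    metal_indices: set[int] = field(default_factory=set)
    coordination: dict[int, list[int]] = field(default_factory=dict)

    def neighbors(self, i: int) -> list[int]:
        out = [b if a == i else a for a, b in self.bonds if i in (a, b)]
        return sorted(out)

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError(f"self-bond on atom {i}")
        self.bonds.add((min(i, j), max(i, j)))

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.bonds


class NoMetalError(ValueError):
    """Raised when a structure contains no metal center."""


class LinkedMetalLimitError(ValueError):
    """Raised when a linked-metal group exceeds the supported size."""


def perceive_bonds(geometry: MolecularGeometry,
                   tolerance_factor: float = DEFAULT_TOLERANCE_FACTOR,
                   ) -> Topology:
    """Perceive bonds: atoms ``i, j`` are bonded iff
    ``d(i, j) <= tolerance_factor * (r_cov(i) + r_cov(j))``.

    Pairs closer than 0.4 Å raise (overlapping atoms).
    """
    if tolerance_factor <= 0:
        raise ValueError("tolerance_factor must be positive")
    coords = geometry.coordinates
    radii = np.array([covalent_radius(e) for e in geometry.elements])
    n = geometry.n_atoms
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    topo = Topology(n_atoms=n)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < MIN_CONTACT:
                raise ValueError(
                    f"atoms {i} ({geometry.elements[i]}) and {j} "
                    f"({geometry.elements[j]}) overlap at "
                    f"{dist[i, j]:.3f} Å"
                )
            if dist[i, j] <= tolerance_factor * (radii[i] + radii[j]):
                topo.add_bond(i, j)
    return topo


def enumerate_angles_dihedrals(topology: Topology) -> Topology:
    """Expand angles and proper dihedrals from the bond graph, in a canonical
    order (lexicographically smallest end first) so outputs are byte-stable.
    """
    nbrs = {i: topology.neighbors(i) for i in range(topology.n_atoms)}
    angles: list[tuple[int, int, int]] = []
    for b in range(topology.n_atoms):
        for a, c in combinations(nbrs[b], 2):
            angles.append((a, b, c) if a < c else (c, b, a))
    angles.sort()
    dihedrals: list[tuple[int, int, int, int]] = []
    for b, c in sorted(topology.bonds):
        for a in nbrs[b]:
            if a == c:
                continue
            for d in nbrs[c]:
                if d == b or d == a:
                    continue
                quad = (a, b, c, d)
                rev = (d, c, b, a)
                canon = min(quad, rev)
                dihedrals.append(canon)
    topology.angles = angles
    topology.dihedrals = sorted(set(dihedrals))
    return topology


def find_metals_and_spheres(geometry: MolecularGeometry,
                            topology: Topology) -> Topology:
    """Locate metal atoms and their coordination spheres.

    At least one metal center is expected; none raises :class:`NoMetalError`.
    """
    metals = {i for i, el in enumerate(geometry.elements) if is_metal(el)}
    if not metals:
        raise NoMetalError(
            "at least one metal center is expected in the molecule"
        )
    topology.metal_indices = metals
    topology.coordination = {m: topology.neighbors(m) for m in sorted(metals)}
    return topology


def linked_metal_groups(topology: Topology,
                        max_size: int = MAX_LINKED_METALS,
                        ) -> list[list[int]]:
    """Partition the metals into linked groups.

    Two metals are linked when they are bonded to each other or share a
    bridging coordinating atom.  Any group larger than ``max_size`` raises
    :class:`LinkedMetalLimitError` naming its metals.
    """
    g = nx.Graph()
    metals = sorted(topology.metal_indices)
    g.add_nodes_from(metals)
    for m1, m2 in combinations(metals, 2):
        if topology.has_bond(m1, m2):
            g.add_edge(m1, m2)
            continue
        shared = set(topology.coordination.get(m1, [])) & set(
            topology.coordination.get(m2, []))
        if shared - topology.metal_indices:
            g.add_edge(m1, m2)
    groups = [sorted(c) for c in nx.connected_components(g)]
    groups.sort()
    for grp in groups:
        if len(grp) > max_size:
            raise LinkedMetalLimitError(
                f"linked metal group {grp} has {len(grp)} metals; "
                f"at most {max_size} linked metals are supported"
            )
    return groups


def build_topology(geometry: MolecularGeometry,
                   tolerance_factor: float = DEFAULT_TOLERANCE_FACTOR,
                   require_metal: bool = True) -> Topology:
    """Full perception pipeline: bonds, angles/dihedrals, metals, validation."""
    topo = perceive_bonds(geometry, tolerance_factor)
    enumerate_angles_dihedrals(topo)
    if require_metal:
        find_metals_and_spheres(geometry, topo)
        linked_metal_groups(topo)
    return topo
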