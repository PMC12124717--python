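"""Synthetic test-data generation: idealized complex geometries, analytic
spring-network Hessians, ESP grids, and dialect-faithful QM file writers.

The spring model is the analytic oracle for the Hessian-projection force
constants.  Each bond contributes the quadratic energy

    E = ½ k_b ((Δu_A − Δu_B)·û)²  +  ½ k_p |P (Δu_A − Δu_B)|²

about the reference geometry (û the bond unit vector, P = I − ûûᵀ), so the
interatomic interaction block is exactly −(k_b ûûᵀ + k_p P), the bond-axis
projection recovers k_b, and the perpendicular stiffness seen by an angle
bend is exactly k_p — giving the closed form 1/kθ = Σ 1/(R² k_p) in Bohr
units.  Generated Hessians are symmetric and translation-invariant by
construction.

ESP grids place points on spherical shells at 1.4–2.0× the van der Waals
radius of each atom, rejecting points that fall inside any atom's inner
shell, with potentials computed exactly from a known generating charge
vector — an inverse problem the charge fit must solve back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._elements import vdw_radius
from .charge_fit import EspGrid
from .constants import BOHR_TO_ANGSTROM
from .qm_io import CartesianHessian, HessianDialect, MolecularGeometry
from .topology import Topology, build_topology

COMPLEX_KINDS = ("octahedral", "square_planar", "linear", "bimetallic",
                 "tris_bidentate")

#: default metal–ligand bond length for ideal complexes, Å
DEFAULT_BOND_LENGTH = 2.10

_AXES = np.array([
    [1.0, 0, 0], [-1.0, 0, 0],
    [0, 1.0, 0], [0, -1.0, 0],
    [0, 0, 1.0], [0, 0, -1.0],
])


def make_ideal_complex(kind: str,
                       metal: str = "Ru",
                       ligand: str = "N",
                       bond_length: float = DEFAULT_BOND_LENGTH,
                       ) -> tuple[MolecularGeometry, Topology]:
    """Build an exact idealized coordination geometry and its topology.

    ``octahedral`` puts six ligand atoms on the Cartesian axes (all cis
    angles exactly 90°, trans exactly 180°); ``square_planar`` four in the
    xy plane; ``linear`` two on ±x; ``bimetallic`` two bonded metals each
    carrying terminal ligands; ``tris_bidentate`` an octahedron whose cis
    ligand pairs are chelated through two-carbon backbones.
    """
    if kind not in COMPLEX_KINDS:
        raise ValueError(f"unknown complex kind {kind!r}; "
                         f"choose from {COMPLEX_KINDS}")
    d = bond_length
    if kind == "octahedral":
        elements = [metal] + [ligand] * 6
        coords = np.vstack([[0.0, 0, 0], d * _AXES])
    elif kind == "square_planar":
        elements = [metal] + [ligand] * 4
        coords = np.vstack([[0.0, 0, 0], d * _AXES[:4]])
    elif kind == "linear":
        elements = [metal] + [ligand] * 2
        coords = np.vstack([[0.0, 0, 0], d * _AXES[:2]])
    elif kind == "bimetallic":
        # two Rh-like centers bonded to each other, each with 4 terminal O
        sep = 2.4
        elements = [metal, metal] + [ligand] * 8
        half = sep / 2.0
        arms = []
        for sign in (-1.0, 1.0):
            cx = sign * half
            arms.extend([
                [cx, d, 0.0], [cx, -d, 0.0], [cx, 0.0, d], [cx, 0.0, -d],
            ])
        coords = np.vstack([[-half, 0, 0], [half, 0, 0], arms])
    else:  # tris_bidentate
        elements = [metal] + [ligand] * 6
        coords = [np.zeros(3)]
        n_pos = d * _AXES
        coords.extend(n_pos)
        # chelate cis pairs (+x,+y), (-x,+z), (-y,-z) through C-C backbones
        pairs = [(0, 2), (1, 4), (3, 5)]
        a_out, b_out = 2.55, 1.35
        for ia, ib in pairs:
            u = _AXES[ia]
            v = _AXES[ib]
            coords.append(a_out * u + b_out * v)
            coords.append(b_out * u + a_out * v)
            elements.extend(["C", "C"])
        coords = np.vstack(coords)
    geom = MolecularGeometry(elements=elements, coordinates=coords,
                             title=f"ideal {kind} complex")
    topo = build_topology(geom)
    return geom, topo


@dataclass
class SpringModel:
    """Bond-spring network with axial constants ``k_b`` and isotropic
    perpendicular stiffnesses ``k_p`` (Hartree/Bohr²) per bond."""

    geometry: MolecularGeometry
    topology: Topology
    k_bond: dict[tuple[int, int], float] = field(default_factory=dict)
    k_perp: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.k_bond:
            if key not in self.topology.bonds:
                raise ValueError(f"spring on non-bond {key}")

    @classmethod
    def uniform(cls, geometry: MolecularGeometry, topology: Topology,
                k_bond: float = 0.25, k_perp: float = 0.05) -> "SpringModel":
        return cls(
            geometry=geometry, topology=topology,
            k_bond={b: k_bond for b in sorted(topology.bonds)},
            k_perp={b: k_perp for b in sorted(topology.bonds)},
        )

    @classmethod
    def random(cls, geometry: MolecularGeometry, topology: Topology,
               rng: np.random.Generator,
               k_bond_range: tuple[float, float] = (0.1, 0.5),
               k_perp_range: tuple[float, float] = (0.02, 0.1),
               ) -> "SpringModel":
        bonds = sorted(topology.bonds)
        kb = rng.uniform(*k_bond_range, size=len(bonds))
        kp = rng.uniform(*k_perp_range, size=len(bonds))
        return cls(geometry=geometry, topology=topology,
                   k_bond=dict(zip(bonds, kb)),
                   k_perp=dict(zip(bonds, kp)))


def make_spring_hessian(model: SpringModel) -> CartesianHessian:
    """Assemble the exact analytic Hessian of the spring network
    (Hartree/Bohr²; bond directions from the Å geometry are unit vectors,
    so no length conversion enters the stiffness blocks)."""
    n = model.geometry.n_atoms
    h = np.zeros((3 * n, 3 * n))
    coords = model.geometry.coordinates
    for (i, j) in sorted(model.topology.bonds):
        u = coords[j] - coords[i]
        u = u / np.linalg.norm(u)
        proj = np.outer(u, u)
        perp = np.eye(3) - proj
        k = model.k_bond.get((i, j), 0.0) * proj + \
            model.k_perp.get((i, j), 0.0) * perp
        si, sj = 3 * i, 3 * j
        h[si:si + 3, si:si + 3] += k
        h[sj:sj + 3, sj:sj + 3] += k
        h[si:si + 3, sj:sj + 3] -= k
        h[sj:sj + 3, si:si + 3] -= k
    return CartesianHessian(matrix=h, n_atoms=n,
                            source_dialect=HessianDialect.PLAIN)


# ---------------------------------------------------------------------------
# Dialect-faithful Hessian writers (oracles for the qm_io readers)

def write_plain_hessian(hessian: CartesianHessian, path: str | Path) -> None:
    lines = ["# Cartesian Hessian, units: Hartree/Bohr^2",
             f"# atoms: {hessian.n_atoms}"]
    for row in hessian.matrix:
        lines.append(" ".join(f"{v: .12e}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fchk_hessian(hessian: CartesianHessian, path: str | Path) -> None:
    """Write the lower-triangular Cartesian force-constant block in the
    Gaussian formatted-checkpoint layout (5 values per line, %16.8E)."""
    side = 3 * hessian.n_atoms
    tri = [hessian.matrix[i, j] for i in range(side) for j in range(i + 1)]
    lines = [f"Cartesian Force Constants                          "
             f"R   N={len(tri):12d}"]
    for start in range(0, len(tri), 5):
        lines.append("".join(f"{v:16.8E}" for v in tri[start:start + 5]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_orca_hessian(hessian: CartesianHessian, path: str | Path) -> None:
    """Write a ``$hessian`` section in the ORCA .hess column-blocked layout
    (blocks of 5 columns; row index leads each data line)."""
    side = 3 * hessian.n_atoms
    lines = ["$orca_hessian_file", "", "$hessian", f"{side}"]
    for start in range(0, side, 5):
        cols = list(range(start, min(start + 5, side)))
        lines.append("".join(f"{c:>19d}" for c in cols))
        for r in range(side):
            vals = "".join(f"{hessian.matrix[r, c]:19.10E}" for c in cols)
            lines.append(f"{r:>7d}{vals}")
    lines.extend(["", "$end"])
    Path(path).write_text("\n".join(lines) + "\n")


def write_hessian(hessian: CartesianHessian, path: str | Path,
                  dialect: HessianDialect | str = HessianDialect.PLAIN,
                  ) -> None:
    dialect = HessianDialect(dialect)
    if dialect is HessianDialect.PLAIN:
        write_plain_hessian(hessian, path)
    elif dialect is HessianDialect.GAUSSIAN_FCHK:
        write_fchk_hessian(hessian, path)
    else:
        write_orca_hessian(hessian, path)


# ---------------------------------------------------------------------------
# ESP grids

def make_esp_grid(geometry: MolecularGeometry,
                  true_charges: np.ndarray,
                  n_points: int,
                  seed: int,
                  shell_factors: tuple[float, ...] = (1.4, 1.6, 1.8, 2.0),
                  ) -> EspGrid:
    """Synthesize an ESP grid whose potentials are the exact Coulomb sums of
    ``true_charges`` (a.u.), sampled on vdW shells around the atoms.

    Deterministic for a fixed ``seed``.  ``n_points`` below 4× the atom
    count raises (the inverse problem would be under-determined).
    """
    n = geometry.n_atoms
    if n_points < 4 * n:
        raise ValueError(f"need at least {4 * n} grid points for {n} atoms")
    true_charges = np.asarray(true_charges, dtype=float)
    if true_charges.size != n:
        raise ValueError("one generating charge per atom required")
    rng = np.random.default_rng(seed)
    radii = np.array([vdw_radius(e) for e in geometry.elements])
    coords = geometry.coordinates
    inner = 1.35 * radii  # rejection shell, slightly inside the first shell
    points: list[np.ndarray] = []
    while len(points) < n_points:
        atom = int(rng.integers(n))
        factor = shell_factors[int(rng.integers(len(shell_factors)))]
        vec = rng.normal(size=3)
        vec /= np.linalg.norm(vec)
        p = coords[atom] + factor * radii[atom] * vec
        d = np.linalg.norm(coords - p, axis=1)
        if (d >= inner).all():
            points.append(p)
    pts = np.array(points)
    dist_bohr = np.linalg.norm(
        pts[:, None, :] - coords[None, :, :], axis=-1) / BOHR_TO_ANGSTROM
    potentials = (true_charges[None, :] / dist_bohr).sum(axis=1)
    return EspGrid(points=pts, potentials=potentials,
                   source=f"synthetic Coulomb grid (seed={seed})")
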