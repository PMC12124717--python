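"""Harmonic bond and angle force constants from the Cartesian Hessian.

The method eigendecomposes the 3×3 interatomic sub-blocks of the QM Hessian
and projects the eigenpairs onto bond-axis and in-plane-perpendicular unit
vectors:

* bond A–B:  ``k_AB = Σ_i (v_i · û_AB)² λ_i`` over the three eigenpairs of
  the (sign-flipped, symmetrized) A–B interaction block;
* angle A–B–C (vertex B):
  ``1/kθ = 1/(R_AB² Σ_i λ_i |û_PA·v_i^AB|) + 1/(R_CB² Σ_i λ_i |û_PC·v_i^CB|)``
  where û_PA ⟂ û_AB and û_PC ⟂ û_CB both lie normal to the angle plane's
  normal û_N, and the R's are bond lengths in Bohr.

Raw constants (Hartree/Bohr², Hartree/rad²) are converted to kcal/mol/Å² and
kcal/(mol·rad²) and doubled so they drop directly into the Amber harmonic
energy expressions K(r−r₀)², K(θ−θ₀)².

Degenerate eigenvalues make the per-eigenvector absolute projections of the
angle formula depend on the arbitrary basis a solver returns inside the
degenerate subspace.  The sums here are therefore evaluated per degenerate
*cluster* as λ·‖Q û_P‖ with Q the cluster's spectral projector — identical to
the per-eigenvector sum for non-degenerate spectra, and basis-independent
(hence rotationally invariant) always.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .atom_typing import AtomTypeAssignment
from .constants import (BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL,
                        HARTREE_PER_BOHR2_TO_KCAL_PER_ANG2)
from .qm_io import CartesianHessian, MolecularGeometry
from .topology import Topology

logger = logging.getLogger(__name__)

#: eigenvalue terms below this (Hartree/Bohr²) are skipped in the angle sums
LAMBDA_MIN = 1e-8

#: relative gap below which eigenvalues are treated as one degenerate cluster
DEGENERACY_RTOL = 1e-8

#: cross-product norm below which an angle is considered collinear
COLLINEAR_TOL = 1e-8

#: harmonic doubling times Hartree/Bohr² -> kcal/mol/Å²
BOND_CONVERSION = 2.0 * HARTREE_PER_BOHR2_TO_KCAL_PER_ANG2

#: harmonic doubling times Hartree/rad² -> kcal/(mol rad²)
ANGLE_CONVERSION = 2.0 * HARTREE_TO_KCALMOL


class DegenerateAngleError(ValueError):
    """Raised for collinear A–B–C triples, where the angle plane is undefined."""


@dataclass
class SubHessian:
    """Sign-flipped, symmetrized 3×3 interaction block with its eigenpairs."""

    block: np.ndarray
    eigenvalues: np.ndarray   # ascending
    eigenvectors: np.ndarray  # columns aligned with eigenvalues

    def projection_sum(self, direction: np.ndarray,
                       lambda_min: float = LAMBDA_MIN) -> float:
        """``Σ λ_i |û·v_i|`` evaluated per degenerate cluster (basis-free).

        Clusters whose eigenvalue falls below ``lambda_min`` are skipped.
        """
        total = 0.0
        for lam, q in self._clusters():
            if lam < lambda_min:
                continue
            total += lam * float(np.linalg.norm(q @ direction))
        return total

    def _clusters(self):
        lams = self.eigenvalues
        vecs = self.eigenvectors
        scale = max(1.0, float(np.abs(lams).max()))
        start = 0
        for i in range(1, 4):
            if i == 3 or lams[i] - lams[start] > DEGENERACY_RTOL * scale:
                sub = vecs[:, start:i]
                yield float(lams[start:i].mean()), sub @ sub.T
                start = i


def interaction_subhessian(hessian: CartesianHessian,
                           a: int, b: int) -> SubHessian:
    """Extract the A–B sub-Hessian: ``−½(H_AB + H_BAᵀ)`` with eigenpairs."""
    if a == b:
        raise ValueError("sub-Hessian requires two distinct atoms")
    hab = hessian.block(a, b)
    hba = hessian.block(b, a)
    # average the two estimates of the interaction block, then symmetrize
    # so the eigenproblem is guaranteed real
    avg = 0.5 * (hab + hba.T)
    block = -0.5 * (avg + avg.T)
    lams, vecs = np.linalg.eigh(block)
    return SubHessian(block=block, eigenvalues=lams, eigenvectors=vecs)


@dataclass
class BondParameter:
    atoms: tuple[int, int]
    k_raw: float        # Hartree/Bohr²
    k_out: float        # kcal/mol/Å², converted and doubled
    r_eq: float         # Å
    involves_metal: bool = False
    stable: bool = True


@dataclass
class AngleParameter:
    atoms: tuple[int, int, int]  # (A, B, C), vertex B
    k_theta_out: float           # kcal/(mol rad²), converted and doubled
    theta_eq: float              # degrees
    involves_metal: bool = False
    # geometry vectors cached for diagnostics
    u_ab: np.ndarray = field(default=None, repr=False)
    u_cb: np.ndarray = field(default=None, repr=False)
    u_n: np.ndarray = field(default=None, repr=False)
    u_pa: np.ndarray = field(default=None, repr=False)
    u_pc: np.ndarray = field(default=None, repr=False)


def bond_force_constant(hessian: CartesianHessian,
                        geometry: MolecularGeometry,
                        a: int, b: int) -> BondParameter:
    """Bond force constant from the A–B sub-Hessian eigenpairs.

    A non-positive raw constant (unstable mode along the bond axis) is
    reported with a warning and ``stable=False`` rather than raised.
    """
    sub = interaction_subhessian(hessian, a, b)
    vec = geometry.coordinates[a] - geometry.coordinates[b]
    r_eq = float(np.linalg.norm(vec))
    u_ab = vec / r_eq
    proj = sub.eigenvectors.T @ u_ab
    k_raw = float(np.sum(proj**2 * sub.eigenvalues))
    stable = k_raw > 0
    if not stable:
        warnings.warn(
            f"non-positive bond force constant {k_raw:.3e} Hartree/Bohr² for "
            f"atoms {a}-{b}: unstable mode along the bond axis",
            stacklevel=2,
        )
    return BondParameter(atoms=(a, b), k_raw=k_raw,
                         k_out=BOND_CONVERSION * k_raw, r_eq=r_eq,
                         stable=stable)


def _angle_vectors(geometry: MolecularGeometry, a: int, b: int, c: int,
                   allow_linear: bool):
    r = geometry.coordinates
    ab = r[a] - r[b]
    cb = r[c] - r[b]
    r_ab = float(np.linalg.norm(ab))
    r_cb = float(np.linalg.norm(cb))
    u_ab = ab / r_ab
    u_cb = cb / r_cb
    cross = np.cross(u_cb, u_ab)
    norm = float(np.linalg.norm(cross))
    if norm < COLLINEAR_TOL:
        if not allow_linear:
            raise DegenerateAngleError(
                f"atoms {a}-{b}-{c} are collinear; the angle plane is undefined"
            )
        # deterministic arbitrary normal: coordinate axis most orthogonal
        # to the bond axis, orthogonalized against it
        axis = np.eye(3)[int(np.argmin(np.abs(u_ab)))]
        u_n = axis - (axis @ u_ab) * u_ab
        u_n /= np.linalg.norm(u_n)
    else:
        u_n = cross / norm
    u_pa = np.cross(u_n, u_ab)
    u_pc = np.cross(u_cb, u_n)
    cos_t = float(np.clip(u_ab @ u_cb, -1.0, 1.0))
    theta = float(np.degrees(np.arccos(cos_t)))
    return u_ab, u_cb, u_n, u_pa, u_pc, r_ab, r_cb, theta


def angle_force_constant(hessian: CartesianHessian,
                         geometry: MolecularGeometry,
                         a: int, b: int, c: int,
                         allow_linear: bool = False) -> AngleParameter:
    """Angle force constant for the A–B–C triple (vertex B).

    Collinear triples raise :class:`DegenerateAngleError` unless
    ``allow_linear`` is set, in which case a deterministic arbitrary normal
    is used (sensible for isotropic perpendicular stiffness, the usual case
    for trans L–M–L angles).
    """
    u_ab, u_cb, u_n, u_pa, u_pc, r_ab, r_cb, theta = _angle_vectors(
        geometry, a, b, c, allow_linear)
    sub_ab = interaction_subhessian(hessian, a, b)
    sub_cb = interaction_subhessian(hessian, c, b)
    s_ab = sub_ab.projection_sum(u_pa)
    s_cb = sub_cb.projection_sum(u_pc)
    if s_ab <= 0 or s_cb <= 0:
        raise ValueError(
            f"no bending stiffness resolvable for angle {a}-{b}-{c}: all "
            f"sub-Hessian eigenvalue terms fall below {LAMBDA_MIN:g}"
        )
    r_ab_bohr = r_ab / BOHR_TO_ANGSTROM
    r_cb_bohr = r_cb / BOHR_TO_ANGSTROM
    inv_k = 1.0 / (r_ab_bohr**2 * s_ab) + 1.0 / (r_cb_bohr**2 * s_cb)
    k_theta = ANGLE_CONVERSION / inv_k
    return AngleParameter(atoms=(a, b, c), k_theta_out=k_theta,
                          theta_eq=theta, u_ab=u_ab, u_cb=u_cb, u_n=u_n,
                          u_pa=u_pa, u_pc=u_pc)


def all_metal_parameters(hessian: CartesianHessian,
                         geometry: MolecularGeometry,
                         topology: Topology,
                         assignment: AtomTypeAssignment | None = None,
                         ) -> tuple[list[BondParameter], list[AngleParameter]]:
    """Seminario parameters for every bond and angle of the topology, each
    tagged with whether it involves a metal atom so assembly can select.

    Exactly linear angles (e.g. trans L–M–L in an octahedron) are evaluated
    with the deterministic arbitrary-normal convention.
    """
    metals = topology.metal_indices
    bonds: list[BondParameter] = []
    for i, j in sorted(topology.bonds):
        p = bond_force_constant(hessian, geometry, i, j)
        p.involves_metal = bool({i, j} & metals)
        bonds.append(p)
    angles: list[AngleParameter] = []
    for a, b, c in topology.angles:
        p = angle_force_constant(hessian, geometry, a, b, c, allow_linear=True)
        p.involves_metal = bool({a, b, c} & metals)
        angles.append(p)
    return bonds, angles
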