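"""Restrained electrostatic-potential (RESP) charge fitting with linear
equality constraints.

The fit minimizes

    χ² = Σ_m ( V_m − Σ_i q_i / r_mi )²  +  a Σ_i ( √(q_i² + b²) − b )

over the grid points m (all quantities in atomic units), subject to exact
linear constraints: total charge, per-atom fixed charges, and intra-class
charge equality for chemically equivalent atoms.  The hyperbolic restraint is
handled by iterative reweighting — at each pass the restraint enters the
normal equations as the diagonal a/√(q_i² + b²) evaluated at the previous
charges — and the constrained linear system is solved via Lagrange
multipliers (a KKT system).  Following standard RESP practice, the restraint
is applied to non-hydrogen atoms that are not charge-fixed.

Equivalence classes are detected by iterated neighborhood refinement on the
bond graph (element plus the sorted multiset of neighbor classes, iterated to
a fixed point), the same invariant-partition scheme used for symmetry
perception in charge-fitting pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import BOHR_TO_ANGSTROM
from .qm_io import ChargeSet, MolecularGeometry
from .topology import Topology

logger = logging.getLogger(__name__)

DEFAULT_RESTRAINT = 0.0005   # a, Hartree·e⁻²  (standard stage-1 strength)
STAGE2_RESTRAINT = 0.001     # a for the optional second stage
RESTRAINT_B = 0.1            # b, e — hyperbola tightness
MAX_ITER = 200
CONVERGENCE = 1e-6           # max |Δq| between reweighting passes, e


class FitConvergenceError(RuntimeError):
    pass


class InfeasibleConstraintsError(ValueError):
    pass


@dataclass
class EspGrid:
    """Electrostatic-potential sample: M points (Å) with potentials (a.u.)."""

    points: np.ndarray      # (M, 3), Å
    potentials: np.ndarray  # (M,), Hartree/e
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.potentials = np.asarray(self.potentials, dtype=float).ravel()
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("grid points must be M×3")
        if self.points.shape[0] != self.potentials.size:
            raise ValueError("one potential per grid point required")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def validate_against(self, geometry: MolecularGeometry,
                         min_separation: float = 0.1) -> None:
        if self.n_points < geometry.n_atoms:
            raise ValueError("fewer grid points than atoms")
        d = np.linalg.norm(
            self.points[:, None, :] - geometry.coordinates[None, :, :], axis=-1)
        if d.min() < min_separation:
            raise ValueError(
                f"grid point within {min_separation} Å of an atom"
            )


@dataclass
class RestraintSpec:
    """Constraint bundle for a fit: fixed per-atom charges, the molecular
    total charge, equivalence classes, and the restraint strength."""

    total_charge: float
    fixed_charges: dict[int, float] = field(default_factory=dict)
    equivalence_classes: list[list[int]] = field(default_factory=list)
    restraint_strength: float = DEFAULT_RESTRAINT

    def validate(self, n_atoms: int) -> None:
        for i in self.fixed_charges:
            if not 0 <= i < n_atoms:
                raise ValueError(f"fixed-charge atom index {i} out of range")
        seen: set[int] = set()
        for cls in self.equivalence_classes:
            for i in cls:
                if not 0 <= i < n_atoms:
                    raise ValueError(f"equivalence atom index {i} out of range")
                if i in seen:
                    raise ValueError(f"atom {i} appears in two classes")
                seen.add(i)
            fixes = {self.fixed_charges[i] for i in cls if i in self.fixed_charges}
            if len(fixes) > 1:
                raise InfeasibleConstraintsError(
                    f"equivalence class {cls} members fixed to different charges"
                )
        if self.restraint_strength < 0:
            raise ValueError("restraint_strength must be ≥ 0")


def equivalence_classes(geometry: MolecularGeometry,
                        topology: Topology,
                        merge_uls: bool = True,
                        uls_atoms: set[int] | None = None,
                        ) -> list[list[int]]:
    """Partition atoms into chemical-environment classes by iterated
    neighborhood refinement.

    With ``merge_uls`` false, atoms carrying unique metal-coordination labels
    (``uls_atoms``) are forced into singleton classes, so each keeps its own
    fitted charge.
    """
    n = geometry.n_atoms
    order = {el: r for r, el in enumerate(sorted(set(geometry.elements)))}
    colors = [order[geometry.elements[i]] for i in range(n)]
    nbrs = {i: topology.neighbors(i) for i in range(n)}
    for _ in range(n):
        keys = [
            (colors[i], tuple(sorted(colors[j] for j in nbrs[i])))
            for i in range(n)
        ]
        rank = {k: r for r, k in enumerate(sorted(set(keys)))}
        new = [rank[k] for k in keys]
        stable = len(set(new)) == len(set(colors))
        colors = new
        if stable:
            break
    if not merge_uls and uls_atoms:
        for i in uls_atoms:
            colors[i] = n + i  # force singleton
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(colors[i], []).append(i)
    return sorted(groups.values())


def _constraint_matrix(n: int, spec: RestraintSpec):
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    total = np.ones(n)
    rows.append(total)
    rhs.append(float(spec.total_charge))
    for i in sorted(spec.fixed_charges):
        row = np.zeros(n)
        row[i] = 1.0
        rows.append(row)
        rhs.append(spec.fixed_charges[i])
    for cls in spec.equivalence_classes:
        anchor = cls[0]
        for other in cls[1:]:
            row = np.zeros(n)
            row[anchor] = 1.0
            row[other] = -1.0
            rows.append(row)
            rhs.append(0.0)
    return np.array(rows), np.array(rhs)


def fit_charges(geometry: MolecularGeometry,
                grid: EspGrid,
                spec: RestraintSpec,
                restrain_hydrogens: bool = False,
                two_stage: bool = False) -> ChargeSet:
    """Fit atomic charges to the ESP grid under the given constraints.

    Returns charges whose sum equals ``spec.total_charge`` and whose fixed
    atoms sit exactly at their targets.  With ``two_stage``, a first pass is
    run without equivalence classes, then atoms outside any multi-member class
    are frozen at their stage-1 values and the classes are refit under the
    stronger conventional stage-2 restraint.
    """
    spec.validate(geometry.n_atoms)
    grid.validate_against(geometry)
    if not two_stage:
        return _fit_single_stage(geometry, grid, spec, restrain_hydrogens)
    stage1 = RestraintSpec(
        total_charge=spec.total_charge,
        fixed_charges=dict(spec.fixed_charges),
        equivalence_classes=[],
        restraint_strength=spec.restraint_strength,
    )
    q1 = _fit_single_stage(geometry, grid, stage1, restrain_hydrogens)
    refit = {i for cls in spec.equivalence_classes if len(cls) > 1 for i in cls}
    fixed = dict(spec.fixed_charges)
    for i in range(geometry.n_atoms):
        if i not in refit and i not in fixed:
            fixed[i] = float(q1.charges[i])
    stage2 = RestraintSpec(
        total_charge=spec.total_charge,
        fixed_charges=fixed,
        equivalence_classes=[c for c in spec.equivalence_classes if len(c) > 1],
        restraint_strength=STAGE2_RESTRAINT,
    )
    return _fit_single_stage(geometry, grid, stage2, restrain_hydrogens)


def _fit_single_stage(geometry: MolecularGeometry,
                      grid: EspGrid,
                      spec: RestraintSpec,
                      restrain_hydrogens: bool) -> ChargeSet:
    n = geometry.n_atoms
    atoms_bohr = geometry.coordinates / BOHR_TO_ANGSTROM
    points_bohr = grid.points / BOHR_TO_ANGSTROM
    rinv = 1.0 / np.linalg.norm(
        points_bohr[:, None, :] - atoms_bohr[None, :, :], axis=-1)
    ata = rinv.T @ rinv
    atb = rinv.T @ grid.potentials

    c_mat, c_rhs = _constraint_matrix(n, spec)
    # infeasibility: rank([C|d]) > rank(C)
    rank_c = np.linalg.matrix_rank(c_mat)
    rank_aug = np.linalg.matrix_rank(np.column_stack([c_mat, c_rhs]))
    if rank_aug > rank_c:
        raise InfeasibleConstraintsError(
            "constraints are mutually inconsistent "
            "(fixed charges conflict with the total charge)"
        )

    restrained = np.array([
        spec.restraint_strength > 0
        and i not in spec.fixed_charges
        and (restrain_hydrogens or geometry.elements[i] != "H")
        for i in range(n)
    ])

    n_c = c_mat.shape[0]
    q = np.zeros(n)
    for iteration in range(MAX_ITER):
        penalty = np.zeros(n)
        if restrained.any():
            penalty[restrained] = spec.restraint_strength / np.sqrt(
                q[restrained] ** 2 + RESTRAINT_B**2)
        kkt = np.zeros((n + n_c, n + n_c))
        kkt[:n, :n] = ata + np.diag(penalty)
        kkt[:n, n:] = c_mat.T
        kkt[n:, :n] = c_mat
        rhs = np.concatenate([atb, c_rhs])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        q_new = sol[:n]
        delta = float(np.abs(q_new - q).max())
        q = q_new
        if delta < CONVERGENCE:
            break
    else:
        resid = float(np.linalg.norm(rinv @ q - grid.potentials))
        raise FitConvergenceError(
            f"restrained fit did not converge in {MAX_ITER} iterations "
            f"(last Δq={delta:.2e}, residual {resid:.3e})"
        )

    # snap the exactly-constrained quantities to their targets: the linear
    # solve honors them to machine precision; they are made bit-exact here
    # for downstream file output.  A class containing a fixed atom pins the
    # whole class; remaining drift is spread uniformly over free atoms, which
    # preserves intra-class equality.
    pinned = dict(spec.fixed_charges)
    for cls in spec.equivalence_classes:
        fixes = [pinned[i] for i in cls if i in pinned]
        if fixes:
            for i in cls:
                pinned[i] = fixes[0]
        else:
            q[cls] = q[cls].mean()
    for i, target in pinned.items():
        q[i] = target
    free = [i for i in range(n) if i not in pinned]
    if free:
        q[free] += (spec.total_charge - q.sum()) / len(free)
    logger.info("RESP fit converged in %d iterations", iteration + 1)
    return ChargeSet(charges=q, method_tag="resp")


def read_esp_grid(path: str | Path, source: str = "") -> EspGrid:
    """Read a plain-text grid: one ``x y z V`` line per point (Å, a.u.)."""
    pts: list[list[float]] = []
    pot: list[float] = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = ln.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 'x y z V'")
        vals = [float(p) for p in parts]
        pts.append(vals[:3])
        pot.append(vals[3])
    return EspGrid(points=np.array(pts), potentials=np.array(pot),
                   source=source or str(path))


def write_esp_grid(grid: EspGrid, path: str | Path) -> None:
    lines = [f"{x:18.10f} {y:18.10f} {z:18.10f} {v:18.10e}"
             for (x, y, z), v in zip(grid.points, grid.potentials)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_constraints(path: str | Path) -> tuple[dict[int, float], float | None]:
    """Read a constraint file: ``atom_index charge`` lines plus an optional
    ``total <Q>`` line.  Indices are zero-based."""
    fixed: dict[int, float] = {}
    total: float | None = None
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = ln.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if parts[0].lower() in ("total", "total_charge"):
            total = float(parts[1])
            continue
        if len(parts) != 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 'atom_index charge'"
            )
        fixed[int(parts[0])] = float(parts[1])
    return fixed, total
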