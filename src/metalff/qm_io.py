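"""Readers for QM program outputs: XYZ geometries, Cartesian Hessians
(Gaussian formatted-checkpoint, ORCA .hess, or plain dense text) and
partial-charge lists.

All readers return the package's internal containers.  Conventions:

* geometries are in Å, atom order is positional and must agree across the
  geometry, Hessian, and charge files — no reordering heuristics are applied;
* Hessians are energy second derivatives in Hartree/Bohr² (the native
  convention of both supported QM codes; the plain dialect carries an explicit
  unit header);
* charges are in units of the elementary charge e.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from ._elements import normalize_symbol

logger = logging.getLogger(__name__)

#: maximum |H - H^T| accepted silently; larger asymmetry is symmetrized with
#: a warning
ASYMMETRY_TOL = 1e-6


class HessianDialect(str, Enum):
    GAUSSIAN_FCHK = "gaussian_fchk"
    ORCA_HESS = "orca_hess"
    PLAIN = "plain"


class ChargeDialect(str, Enum):
    TWO_COLUMN = "two_column"
    MOL2 = "mol2"


class ParseError(ValueError):
    """Raised when an input file does not match its declared dialect."""


@dataclass
class MolecularGeometry:
    """Elements and Cartesian coordinates (Å) of one molecule."""

    elements: list[str]
    coordinates: np.ndarray  # (N, 3), Å
    total_charge: int | None = None
    title: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an N×3 array")
        if len(self.elements) != self.coordinates.shape[0]:
            raise ValueError(
                f"{len(self.elements)} elements but "
                f"{self.coordinates.shape[0]} coordinate rows"
            )
        if len(self.elements) < 1:
            raise ValueError("geometry must contain at least one atom")
        self.elements = [normalize_symbol(e) for e in self.elements]

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))


@dataclass
class CartesianHessian:
    """Dense 3N×3N matrix of energy second derivatives, Hartree/Bohr²."""

    matrix: np.ndarray
    n_atoms: int
    source_dialect: HessianDialect = HessianDialect.PLAIN

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        side = 3 * self.n_atoms
        if self.matrix.shape != (side, side):
            raise ValueError(
                f"Hessian must be {side}×{side} for {self.n_atoms} atoms, "
                f"got {self.matrix.shape}"
            )
        asym = float(np.abs(self.matrix - self.matrix.T).max())
        if asym > ASYMMETRY_TOL:
            warnings.warn(
                f"Hessian asymmetry {asym:.3e} exceeds {ASYMMETRY_TOL:.0e}; "
                "symmetrizing (H+H^T)/2",
                stacklevel=2,
            )
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    def block(self, a: int, b: int) -> np.ndarray:
        """3×3 block coupling the displacements of atoms ``a`` and ``b``."""
        if not (0 <= a < self.n_atoms and 0 <= b < self.n_atoms):
            raise IndexError(f"atom index out of range: ({a}, {b})")
        return self.matrix[3 * a : 3 * a + 3, 3 * b : 3 * b + 3]


@dataclass
class ChargeSet:
    """Per-atom partial charges in e."""

    charges: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float).ravel()

    def __len__(self) -> int:
        return self.charges.size

    @property
    def total(self) -> float:
        return float(self.charges.sum())

    def check_total(self, total_charge: int, tol: float = 1e-4) -> None:
        if abs(self.total - total_charge) > tol:
            raise ValueError(
                f"charges sum to {self.total:.6f}, expected {total_charge}"
            )


# ---------------------------------------------------------------------------
# XYZ

def read_xyz(path: str | Path) -> MolecularGeometry:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` body).

    Atom order is preserved.  A count/body mismatch or an unresolvable element
    symbol raises :class:`ParseError`.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: line 1 must be an integer atom count") from exc
    title = lines[1].strip() if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise ParseError(
            f"{path}: header declares {n} atoms but body has {len(body)} "
            f"(first missing at line {len(body) + 3})"
        )
    elements: list[str] = []
    coords = np.empty((n, 3))
    for i, ln in enumerate(body[:n]):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: malformed atom line {i + 3}: {ln!r}")
        try:
            elements.append(normalize_symbol(parts[0]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 3}: {exc}") from exc
        try:
            coords[i] = [float(x) for x in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 3}: bad coordinate") from exc
    return MolecularGeometry(elements=elements, coordinates=coords, title=title)


def write_xyz(geometry: MolecularGeometry, path: str | Path,
              precision: int = 8) -> None:
    """Write ``geometry`` as a standard XYZ file."""
    lines = [str(geometry.n_atoms), geometry.title]
    for el, xyz in zip(geometry.elements, geometry.coordinates):
        x, y, z = xyz
        lines.append(f"{el:<2s} {x:>{precision + 7}.{precision}f} "
                     f"{y:>{precision + 7}.{precision}f} "
                     f"{z:>{precision + 7}.{precision}f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hessians

_FCHK_MARKER = "Cartesian Force Constants"


def _unpack_lower_triangle(values: Sequence[float], side: int) -> np.ndarray:
    expected = side * (side + 1) // 2
    if len(values) != expected:
        raise ParseError(
            f"lower triangle needs {expected} values for side {side}, "
            f"got {len(values)}"
        )
    mat = np.zeros((side, side))
    it = iter(values)
    for i in range(side):
        for j in range(i + 1):
            mat[i, j] = next(it)
    return mat + np.tril(mat, -1).T


def _read_fchk_hessian(text: str, path: str | Path) -> np.ndarray:
    lines = text.splitlines()
    start = None
    count = None
    for idx, ln in enumerate(lines):
        if ln.startswith(_FCHK_MARKER):
            start = idx + 1
            count = int(ln.split("N=")[1])
            break
    if start is None:
        raise ParseError(f"{path}: marker {_FCHK_MARKER!r} not found")
    values: list[float] = []
    for ln in lines[start:]:
        parts = ln.split()
        if not parts:
            continue
        try:
            values.extend(float(p) for p in parts)
        except ValueError:
            break  # next fchk section header
        if len(values) >= count:
            break
    if len(values) < count:
        raise ParseError(
            f"{path}: section declares {count} values, found {len(values)}"
        )
    values = values[:count]
    # count = 3N(3N+1)/2  ->  3N
    side = int(round((np.sqrt(8 * count + 1) - 1) / 2))
    return _unpack_lower_triangle(values, side)


def _read_orca_hessian(text: str, path: str | Path) -> np.ndarray:
    lines = text.splitlines()
    start = None
    for idx, ln in enumerate(lines):
        if ln.strip() == "$hessian":
            start = idx + 1
            break
    if start is None:
        raise ParseError(f"{path}: marker '$hessian' not found")
    try:
        side = int(lines[start].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: bad $hessian dimension line") from exc
    mat = np.full((side, side), np.nan)
    i = start + 1
    while np.isnan(mat).any():
        if i >= len(lines):
            raise ParseError(f"{path}: $hessian block truncated")
        header = lines[i].split()
        if not header:
            i += 1
            continue
        try:
            cols = [int(h) for h in header]
        except ValueError as exc:
            raise ParseError(f"{path}: expected column-index header, "
                             f"got {lines[i]!r}") from exc
        i += 1
        for _ in range(side):
            parts = lines[i].split()
            row = int(parts[0])
            vals = [float(p) for p in parts[1:]]
            if len(vals) != len(cols):
                raise ParseError(f"{path}: row {row} has {len(vals)} values "
                                 f"for {len(cols)} columns")
            mat[row, cols] = vals
            i += 1
    return mat


def _read_plain_hessian(text: str, path: str | Path) -> np.ndarray:
    rows: list[list[float]] = []
    for ln in text.splitlines():
        stripped = ln.strip()
        if not stripped or stripped.startswith("#"):
            continue
        rows.append([float(p) for p in stripped.split()])
    if not rows:
        raise ParseError(f"{path}: no matrix data found")
    side = len(rows)
    if any(len(r) != side for r in rows):
        raise ParseError(f"{path}: matrix is not square")
    return np.array(rows)


def read_hessian(path: str | Path,
                 dialect: HessianDialect | str,
                 n_atoms: int | None = None) -> CartesianHessian:
    """Read a Cartesian Hessian in Hartree/Bohr².

    ``dialect`` selects the file layout: ``gaussian_fchk`` (lower-triangular
    Cartesian force-constant block of a formatted checkpoint), ``orca_hess``
    (column-blocked ``$hessian`` section), or ``plain`` (dense whitespace
    matrix with ``#`` comment/unit headers).  When ``n_atoms`` is given from a
    companion geometry, a mismatch raises.
    """
    dialect = HessianDialect(dialect)
    text = Path(path).read_text()
    if dialect is HessianDialect.GAUSSIAN_FCHK:
        mat = _read_fchk_hessian(text, path)
    elif dialect is HessianDialect.ORCA_HESS:
        mat = _read_orca_hessian(text, path)
    else:
        mat = _read_plain_hessian(text, path)
    if mat.shape[0] % 3:
        raise ParseError(f"{path}: matrix side {mat.shape[0]} is not 3N")
    n = mat.shape[0] // 3
    if n_atoms is not None and n != n_atoms:
        raise ParseError(
            f"{path}: Hessian is for {n} atoms, geometry has {n_atoms}"
        )
    return CartesianHessian(matrix=mat, n_atoms=n, source_dialect=dialect)


# ---------------------------------------------------------------------------
# Charges

def read_charges(path: str | Path,
                 dialect: ChargeDialect | str = ChargeDialect.TWO_COLUMN,
                 geometry: MolecularGeometry | None = None,
                 method_tag: str = "") -> ChargeSet:
    """Read per-atom charges from a two-column (``El q``) list or a TRIPOS
    mol2 charge column, in the geometry's atom order.

    When a ``geometry`` is supplied, the atom count must match and, if
    ``geometry.total_charge`` is set, the charge sum is validated to 1e-4 e.
    """
    dialect = ChargeDialect(dialect)
    text = Path(path).read_text()
    charges: list[float] = []
    if dialect is ChargeDialect.TWO_COLUMN:
        for lineno, ln in enumerate(text.splitlines(), 1):
            stripped = ln.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 'El q'")
            try:
                charges.append(float(parts[1].replace("−", "-")))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric charge {parts[1]!r}"
                ) from exc
    else:
        in_atoms = False
        for ln in text.splitlines():
            stripped = ln.strip()
            if stripped.startswith("@<TRIPOS>"):
                in_atoms = stripped == "@<TRIPOS>ATOM"
                continue
            if in_atoms and stripped:
                parts = stripped.split()
                if len(parts) < 9:
                    raise ParseError(
                        f"{path}: mol2 ATOM record without charge column: "
                        f"{stripped!r}"
                    )
                try:
                    charges.append(float(parts[8]))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: non-numeric mol2 charge {parts[8]!r}"
                    ) from exc
    result = ChargeSet(charges=np.array(charges), method_tag=method_tag)
    if geometry is not None:
        if len(result) != geometry.n_atoms:
            raise ParseError(
                f"{path}: {len(result)} charges for {geometry.n_atoms} atoms"
            )
        if geometry.total_charge is not None:
            result.check_total(geometry.total_charge)
    return result
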