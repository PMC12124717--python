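# Methods

## The bonded model

`metalff` describes a metal center with explicit harmonic bond and angle
terms plus point charges. Metal-involving dihedral torsions are neglected
(written as explicit zero-barrier records so simulation engines see complete
topology), and metal Lennard-Jones terms are not fitted — they are taken
from UFF, on the grounds that electrostatics dominates the nonbonded
environment of most coordinated metals. The target energy expression is the
Amber form

    U = Σ K_r (r − r_eq)² + Σ K_θ (θ − θ_eq)² + torsions + LJ + Coulomb

which is why all Hessian-derived constants are **doubled** after unit
conversion: the eigenprojection yields the ½k of a physicist's harmonic
expansion, while Amber's K multiplies the squared displacement without the
½. Output file headers state the convention.

## Hessian-projection (Seminario) force constants

For atoms A, B the interatomic block H_AB (rows 3A..3A+2, columns 3B..3B+2)
of the mass-unweighted Cartesian Hessian carries the curvature coupling
their displacements. The sub-Hessian used here is
−½(S + Sᵀ) with S = ½(H_AB + H_BAᵀ): the two estimates of the interaction
block are averaged and the result symmetrized so the eigenproblem is real.
(For an exactly symmetric input Hessian this reduces to the symmetrized
negative block −½(H_AB + H_ABᵀ).) With eigenpairs (λ_i, v̂_i):

* bond: k_AB = Σ_i (v̂_i·û_AB)² λ_i, with û_AB the bond unit vector. The
  squared projection makes this the quadratic form û_ABᵀ(−H̃_AB)û_AB —
  basis-independent by construction.
* angle A–B–C: û_N = (û_CB×û_AB)/‖·‖ is the plane normal, û_PA = û_N×û_AB
  and û_PC = û_CB×û_N the in-plane perpendiculars, and

      1/k_θ = 1/(R_AB² Σ_i λ_i|û_PA·v̂_i^AB|) + 1/(R_CB² Σ_i λ_i|û_PC·v̂_i^CB|)

  with bond lengths in Bohr, giving k_θ in Hartree/rad².

Unit constants: 627.509474 kcal/mol per Hartree, 0.529177211 Å per Bohr;
bond constants are multiplied by 2 × 627.509474/0.529177211² ≈ 2 × 2240.88,
angle constants by 2 × 627.509474.

### Numerical choices

* **Degenerate eigenvalues.** The absolute-projection sum of the angle
  formula is ambiguous when eigenvalues coincide: any orthonormal basis of
  the degenerate subspace is a valid eigenvector set, and the sum of
  absolute projections varies with that basis by up to √2. The sums here
  are therefore evaluated per degenerate cluster (relative gap ≤ 1e−8) as
  λ·‖Q û_P‖, Q the cluster's spectral projector. This is identical to the
  per-eigenvector sum whenever the spectrum is non-degenerate, and it is
  basis-independent always — which is what makes the angle constants exactly
  rotation-invariant and lets the spring-network oracle hold to machine
  precision (an isotropic bond spring has an exactly twofold-degenerate
  perpendicular eigenspace).
* **Near-zero eigenvalues.** Cluster terms with λ < 1e−8 Hartree/Bohr² are
  skipped; if every term of a sum falls below the threshold the angle has no
  resolvable bending stiffness and an error is raised.
* **Collinear angles.** At θ = 180° (cross-product norm < 1e−8) the plane
  normal is undefined. The per-angle function raises a degenerate-angle
  error by default. The whole-molecule driver instead evaluates linear
  angles with a deterministic arbitrary normal (the coordinate axis most
  orthogonal to the bond, Gram-Schmidt-orthogonalized): for an isotropic
  perpendicular stiffness — the physically relevant case for trans L–M–L
  angles in octahedra — the result is independent of that choice, and every
  topology angle receives a parameter, which the coverage guarantee
  requires.
* **Non-positive bond constants** (unstable mode along the bond) are
  reported with a warning and flagged rather than raised, since they can
  appear for weakly bound contacts in real Hessians.
* Equilibrium bond lengths and angles are read from the input optimized
  geometry; no re-minimization is performed.

## Unique labeling of coordinating atoms

Metals are processed in atom-index order. The first metal's coordinating
atoms draw suffixes from the digits (N1, N2, …), the second's from uppercase
letters (NA, NB, …), the third's from lowercase letters, and later metals
from two-character digit+letter combinations; a label that would collide
with an existing one advances the alphabet. An atom bridging two metals
keeps the label assigned by the first metal that reaches it; metal atoms
themselves carry their element symbol as type. Labels are capped at four
characters for Amber-format compatibility, and more than 99 coordinating
atoms is an error. The scheme is a deterministic function of the input
geometry, so repeated runs produce byte-identical files.

Base types for the organic scaffold are a deliberately simple
element+coordination-number heuristic (`c3`, `n2`, …) with a per-atom
override hook, because full GAFF perception is an external tool's job in the
workflow this package automates, not part of its contribution. When the
override is used, database lookups key on the supplied (real GAFF) types.

## Topology perception

Atoms are bonded when their distance is at most `tolerance_factor` × the sum
of their covalent radii (embedded Cordero-style table; default factor 1.25,
user-overridable). Pairs closer than 0.4 Å are rejected as overlapping.
Angles are all neighbor pairs about a vertex; dihedrals all bonded 4-paths;
both in a canonical lexicographic order. Two metals are "linked" when
directly bonded or sharing a non-metal bridging donor; linked groups larger
than four metals are rejected, matching the tool's validated domain. η-bonded
ring ligands are handled as plain per-atom bonds (every ring atom within the
distance criterion bonds to the metal); no centroid dummy atoms are created.

## Hybrid assembly

Per term: metal-involving → Seminario value; otherwise database hit →
database value; otherwise Seminario fallback, flagged as missing in the
database. Metal dihedrals are zero-barrier (PK=0, PN=1, phase=0) with Amber
default 1–4 scaling columns (SCEE 1.2, SCNB 2.0). Metal LJ: UFF vdW distance
halved (the Amber NONBON column is R_min/2), well depth unchanged; the
embedded UFF-style subset covers the common metals, and an absent element is
an explicit error suggesting a manual entry. Masses come from an embedded
isotopic-average table. Every topology term must resolve to exactly one
entry with a single provenance tag (seminario / database / zeroed / uff) —
the assembly errors out rather than emit an incomplete file.

## Restrained ESP charge fitting

The fit minimizes Σ_m (V_m − Σ_i q_i/r_mi)² + a Σ_i (√(q_i²+b²) − b) in
atomic units over the supplied grid, subject to exact linear equality
constraints: total charge, imposed per-atom charges, and intra-class
equality. Defaults follow the standard RESP convention: a = 0.0005 a.u.
(0.001 in the optional second stage), b = 0.1 e, hydrogens and fixed atoms
unrestrained, single-stage by default. The hyperbolic restraint is handled
by iterative reweighting of the KKT (Lagrange-multiplier) system until
max |Δq| < 1e−6 e, with a 200-iteration cap; infeasible constraint sets are
detected by a rank test before solving. Converged charges are snapped so
fixed atoms, class equalities, and the total are exact to the last bit.
Equivalence classes come from iterated neighborhood refinement (element +
sorted multiset of neighbor classes to a fixed point); uniquely-labeled
coordinating atoms can be forced into singletons when the user disables
symmetry merging.

## What the synthetic data emulates — and what it does not

The fixtures module stands in for the QM outputs a user would bring:

* **Idealized complexes** (octahedral, square-planar, linear, bimetallic,
  tris-bidentate chelate) have exact 90°/180° coordination geometry with a
  2.10 Å default metal–ligand distance. They exercise connectivity, typing,
  counting, and file-writing logic but are not DFT-optimized structures.
* **Spring-network Hessians** assign each bond an axial constant k_b and an
  isotropic perpendicular stiffness k_p (defaults 0.25 / 0.05 Hartree/Bohr²,
  the magnitude range of real metal–ligand blocks). They make the projection
  formulas exactly invertible — the bond projection returns k_b and the
  angle reciprocal sum equals 1/k_θ = Σ 1/(R²k_p) — which is what the oracle
  tests assert. Real Hessians add inter-bond coupling, anharmonicity-induced
  asymmetry, and soft modes; passing the oracles shows the formulas are
  implemented correctly, not that the bonded model reproduces ab initio
  dynamics.
* **ESP grids** sample shells at 1.4–2.0× vdW radii with potentials computed
  exactly from a generating charge vector, so unconstrained recovery is
  well-posed. Real molecular ESPs are not exactly representable by atomic
  point charges, which is precisely why the restraint and constraints exist.

Problem sizes used throughout the suite (7–13 atoms, ≤ 100 random networks,
400–800 grid points) keep every oracle exact and the whole suite fast; the
method's cost grows only polynomially with system size.

## Known limitations

* No shared-atom correction for angle force constants (the modified
  Seminario scheme); the hybrid split minimizes the issue by taking
  non-metal terms from databases, but strained chelates may still benefit
  from such corrections.
* The base typer is a heuristic, not GAFF perception; for production use on
  organic scaffolds, supply a type override from a dedicated typing tool.
* Bond perception is purely geometric; no bond orders, aromaticity, or
  formal-charge bookkeeping.
* Gaussian log-file Hessian layout is not parsed — use the formatted
  checkpoint, ORCA `.hess`, or plain dense text.
* The `.lib` writer emits a minimal atoms+connectivity entry, not the full
  leap internal table set.
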