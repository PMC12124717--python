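# metalff

Automated bonded-model force-field parametrization of metal-containing
molecules, for computational chemists who need Amber-compatible parameters
for coordination complexes that no transferable force field covers.

Classical force fields such as GAFF or Amber describe organic molecules well
but have no parameters for metal centers, and generic typing collapses all
chemically distinct metal–ligand terms onto a single shared entry (every
N–M–N angle of an octahedron gets one equilibrium value, distorting the
coordination sphere). `metalff` addresses both problems:

* **Hessian-projection force constants.** Harmonic bond and angle constants
  for every metal-involving term are derived from the QM Cartesian Hessian
  (the Seminario scheme). For a bond A–B, the 3×3 interatomic sub-block of
  the Hessian is sign-flipped, symmetrized, and eigendecomposed, and

  $$k_{AB} = \sum_{i=1}^{3} (\hat v_i^{AB} \cdot \hat u_{AB})^2\, \lambda_i^{AB}$$

  with $\hat u_{AB}$ the bond unit vector. For an angle A–B–C, unit vectors
  $\hat u_{PA} \perp \hat u_{AB}$ and $\hat u_{PC} \perp \hat u_{CB}$ in the
  plane-normal construction give

  $$\frac{1}{k_\theta} = \frac{1}{R_{AB}^2 \sum_i \lambda_i^{AB} |\hat u_{PA}\cdot \hat v_i^{AB}|}
      + \frac{1}{R_{CB}^2 \sum_i \lambda_i^{CB} |\hat u_{PC}\cdot \hat v_i^{CB}|}.$$

  Constants are converted from Hartree/Bohr² to kcal/mol/Å² (bonds) and
  kcal/(mol·rad²) (angles) and doubled so they drop directly into the Amber
  forms $K(r-r_0)^2$, $K(\theta-\theta_0)^2$.
* **Unique labeling of coordinating atoms.** Every atom directly bonded to a
  metal receives its own atom type (N1…N6 for the first metal's donors,
  NA, NB, … for a second metal's), so each metal bond/angle resolves to its
  own parameter entry — no shortage, no forced degeneracy.
* **Hybrid assembly.** Only metal-involving terms are taken from the QM
  Hessian; the rest of the molecule is looked up in a transferable database
  (frcmod/dat syntax), with a Seminario fallback for terms the database
  lacks. Metal dihedrals are written as explicit zero-barrier terms; metal
  Lennard-Jones parameters come from UFF with the vdW distance halved to the
  Amber R_min/2 convention.
* **Constrained restrained-ESP charges.** Least-squares charge fitting to an
  ESP grid with a hyperbolic restraint and exact linear constraints: the
  molecular total, imposed per-atom charges (e.g. a physically sensible
  positive metal charge), and equality within chemically equivalent atom
  classes detected by iterated neighborhood refinement.

Inputs are an optimized geometry (XYZ), the Cartesian Hessian (Gaussian
formatted-checkpoint, ORCA `.hess`, or plain dense text), and optionally a
charge list, a parameter database, and an ESP grid. Outputs are Amber
`frcmod`, TRIPOS `mol2`, PDB, and optionally a minimal leap `.lib` file.

## Worked example

Parametrize an idealized octahedral RuN₆ complex whose Hessian is an exact
spring network (axial constant 0.25 Hartree/Bohr², perpendicular 0.05):

```sh
metalff parametrize --xyz ru6n.xyz --hessian ru6n.hess \
    --hessian-dialect orca --charges ru6n.charges --out params
```

prints

```
atoms: 7
bonds: 6  angles: 15  dihedrals: 0
bond keys: 6  angle keys: 15  dihedral keys: 0
provenance: seminario: 21  database: 0  uff: 1  zeroed: 0  default_lj: 6
missing in database: none
files: metalff.frcmod, metalff.mol2, metalff.pdb
```

All 6 bonds and all 15 N–Ru–N angles get their own key (unique labeling at
work: with `--no-uls` the same run collapses to 1 bond key and 1 angle key),
and all 21 constants are Hessian-derived. The frcmod opens with

```
MASS
Ru    101.070
N1     14.007
...
BOND
N1-Ru    1120.439    2.1000
```

where 1120.439 kcal/mol/Å² is exactly 2 × 2240.88 × 0.25 — the axial spring
constant recovered through the eigenprojection and converted/doubled — and
2.1000 Å is the input bond length. A constrained charge fit that imposes
+1.45 e on the metal of this +2 complex,

```sh
metalff charges --xyz ru6n.xyz --grid ru6n.esp \
    --constraints ru6n.constraints --out resp
```

prints

```
total charge: 2.000000
Ru  1.450000
N   0.091667
...
```

the metal exactly at its imposed charge, the remainder redistributed over
the six equivalent donors with the total conserved.

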