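"""Hessian-projection force constants against analytic spring oracles."""

import numpy as np
import pytest

from metalff import (CartesianHessian, MolecularGeometry,
                     all_metal_parameters, angle_force_constant, assign_types,
                     bond_force_constant, build_topology,
                     interaction_subhessian)
from metalff.constants import BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL
from metalff.fixtures import (SpringModel, make_ideal_complex,
                              make_spring_hessian)
from metalff.seminario import BOND_CONVERSION, DegenerateAngleError

from conftest import random_rotation


def two_atom_spring(k=0.25, axis=(1.0, 0.0, 0.0), length=1.5):
    """Analytic two-atom spring along ``axis`` with only axial stiffness."""
    axis = np.asarray(axis) / np.linalg.norm(axis)
    g = MolecularGeometry(elements=["C", "C"],
                          coordinates=[[0, 0, 0], length * axis])
    kmat = k * np.outer(axis, axis)
    h = np.zeros((6, 6))
    h[:3, :3] = h[3:, 3:] = kmat
    h[:3, 3:] = h[3:, :3] = -kmat
    return g, CartesianHessian(matrix=h, n_atoms=2)


class TestSubHessian:
    def test_ideal_spring_block_and_eigenvalues(self):
        g, h = two_atom_spring(k=0.25)
        sub = interaction_subhessian(h, 0, 1)
        np.testing.assert_allclose(sub.block, 0.25 * np.diag([1, 0, 0]),
                                   atol=1e-15)
        np.testing.assert_allclose(sub.eigenvalues, [0, 0, 0.25], atol=1e-15)

    def test_order_independent_eigenvalues(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 6))
        h = CartesianHessian(matrix=a + a.T, n_atoms=2)
        s1 = interaction_subhessian(h, 0, 1)
        s2 = interaction_subhessian(h, 1, 0)
        np.testing.assert_allclose(s1.eigenvalues, s2.eigenvalues, atol=1e-12)

    def test_eigenvalues_match_characteristic_polynomial(self):
        # independent oracle: roots of det(B - x I) via numpy.roots
        rng = np.random.default_rng(7)
        a = rng.normal(size=(6, 6))
        h = CartesianHessian(matrix=a + a.T, n_atoms=2)
        sub = interaction_subhessian(h, 0, 1)
        b = sub.block
        # characteristic polynomial of a 3x3 symmetric matrix
        c2 = -np.trace(b)
        c1 = 0.5 * (np.trace(b) ** 2 - np.trace(b @ b))
        c0 = -np.linalg.det(b)
        roots = np.sort(np.real(np.roots([1.0, c2, c1, c0])))
        np.testing.assert_allclose(sub.eigenvalues, roots, atol=1e-10)

    def test_eigenvectors_orthonormal_and_consistent(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(6, 6))
        h = CartesianHessian(matrix=a + a.T, n_atoms=2)
        sub = interaction_subhessian(h, 0, 1)
        v = sub.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(3), atol=1e-12)
        for lam, vec in zip(sub.eigenvalues, v.T):
            assert np.linalg.norm(sub.block @ vec - lam * vec) < 1e-8

    def test_out_of_range_index(self):
        _, h = two_atom_spring()
        with pytest.raises(IndexError):
            interaction_subhessian(h, 0, 5)


class TestBondConstant:
    def test_spring_recovered_and_converted(self):
        g, h = two_atom_spring(k=0.25)
        p = bond_force_constant(h, g, 0, 1)
        assert p.k_raw == pytest.approx(0.25, rel=1e-12)
        # 2 x 627.509474 / 0.529177211^2 ~= 2 x 2240.88
        assert p.k_out == pytest.approx(2 * 2240.88 * 0.25, rel=1e-4)
        assert p.k_out == pytest.approx(BOND_CONVERSION * 0.25, rel=1e-12)
        assert p.r_eq == pytest.approx(1.5)

    def test_axis_orthogonal_to_stiffness_gives_zero(self):
        g, h = two_atom_spring(k=0.25, axis=(1, 0, 0))
        g_perp = MolecularGeometry(elements=["C", "C"],
                                   coordinates=[[0, 0, 0], [0, 1.5, 0]])
        with pytest.warns(UserWarning, match="non-positive"):
            p = bond_force_constant(h, g_perp, 0, 1)
        assert p.k_raw == pytest.approx(0.0, abs=1e-14)
        assert not p.stable

    def test_atom_swap_symmetry(self):
        g, h = two_atom_spring(k=0.31, axis=(1, 2, 3))
        p1 = bond_force_constant(h, g, 0, 1)
        p2 = bond_force_constant(h, g, 1, 0)
        assert p1.k_out == pytest.approx(p2.k_out, rel=1e-12)
        assert p1.r_eq == pytest.approx(p2.r_eq, rel=1e-12)


class TestAngleConstant:
    def test_symmetric_closed_form(self, octahedral_spring):
        geom, topo, model, h = octahedral_spring
        p = angle_force_constant(h, geom, 1, 0, 3)  # cis N-Ru-N
        r_bohr = 2.10 / BOHR_TO_ANGSTROM
        inv_k = 2.0 / (r_bohr**2 * 0.05)
        expected = 2.0 * HARTREE_TO_KCALMOL / inv_k
        assert p.k_theta_out == pytest.approx(expected, rel=1e-10)
        assert p.theta_eq == pytest.approx(90.0)

    def test_perpendicular_vector_construction(self, octahedral_spring):
        geom, _, _, h = octahedral_spring
        p = angle_force_constant(h, geom, 1, 0, 3)
        assert abs(p.u_pa @ p.u_ab) < 1e-10
        assert abs(p.u_pc @ p.u_cb) < 1e-10
        assert abs(p.u_n @ p.u_ab) < 1e-10
        assert abs(p.u_n @ p.u_cb) < 1e-10

    def test_collinear_raises(self, octahedral_spring):
        geom, _, _, h = octahedral_spring
        with pytest.raises(DegenerateAngleError, match="collinear"):
            angle_force_constant(h, geom, 1, 0, 2)  # trans N-Ru-N

    def test_exchange_symmetry(self, octahedral_spring):
        geom, _, _, h = octahedral_spring
        p1 = angle_force_constant(h, geom, 1, 0, 3)
        p2 = angle_force_constant(h, geom, 3, 0, 1)
        assert p1.k_theta_out == pytest.approx(p2.k_theta_out, rel=1e-12)


def random_network(rng):
    kind = ("octahedral", "square_planar", "tris_bidentate")[
        int(rng.integers(3))]
    geom, topo = make_ideal_complex(kind)
    model = SpringModel.random(geom, topo, rng)
    return geom, topo, model, make_spring_hessian(model)


class TestSpringNetworkOracles:
    def test_bond_constants_recovered_over_random_networks(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            geom, topo, model, h = random_network(rng)
            for (i, j), kb in model.k_bond.items():
                p = bond_force_constant(h, geom, i, j)
                assert p.k_raw == pytest.approx(kb, rel=1e-10)

    def test_metal_angle_closed_form_over_random_networks(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            geom, topo, model, h = random_network(rng)
            r = geom.coordinates
            for a, b, c in topo.angles:
                u1 = r[a] - r[b]
                u2 = r[c] - r[b]
                cosang = u1 @ u2 / np.linalg.norm(u1) / np.linalg.norm(u2)
                if abs(abs(cosang) - 1) < 1e-10:
                    continue  # linear angles handled separately
                kp_ab = model.k_perp[tuple(sorted((a, b)))]
                kp_cb = model.k_perp[tuple(sorted((c, b)))]
                r_ab = np.linalg.norm(u1) / BOHR_TO_ANGSTROM
                r_cb = np.linalg.norm(u2) / BOHR_TO_ANGSTROM
                inv_k = 1 / (r_ab**2 * kp_ab) + 1 / (r_cb**2 * kp_cb)
                expected = 2 * HARTREE_TO_KCALMOL / inv_k
                p = angle_force_constant(h, geom, a, b, c)
                assert p.k_theta_out == pytest.approx(expected, rel=1e-8)

    def test_rotational_invariance(self):
        rng = np.random.default_rng(11)
        geom, topo, model, h = random_network(rng)
        ref_bonds = {b: bond_force_constant(h, geom, *b).k_raw
                     for b in sorted(topo.bonds)}
        bent = [x for x in topo.angles
                if abs(abs(np.cos(np.radians(
                    angle_force_constant(h, geom, *x, allow_linear=True)
                    .theta_eq))) - 1) > 1e-8]
        ref_angles = {x: angle_force_constant(h, geom, *x).k_theta_out
                      for x in bent}
        for _ in range(5):
            rot = random_rotation(rng)
            coords = geom.coordinates @ rot.T
            g2 = MolecularGeometry(elements=geom.elements, coordinates=coords)
            big = np.kron(np.eye(geom.n_atoms), rot)
            h2 = CartesianHessian(matrix=big @ h.matrix @ big.T,
                                  n_atoms=geom.n_atoms)
            for b, k in ref_bonds.items():
                assert bond_force_constant(h2, g2, *b).k_raw == \
                    pytest.approx(k, rel=1e-8, abs=1e-10)
            for x, k in ref_angles.items():
                assert angle_force_constant(h2, g2, *x).k_theta_out == \
                    pytest.approx(k, rel=1e-8)

    def test_positivity_on_spring_models(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            geom, topo, model, h = random_network(rng)
            bonds, angles = all_metal_parameters(
                h, geom, topo, assign_types(geom, build_topology(geom)))
            assert all(p.k_out >= 0 for p in bonds)
            assert all(p.k_theta_out >= 0 for p in angles)


class TestAllMetalParameters:
    def test_octahedron_counts_and_tags(self, octahedral_spring):
        geom, topo, model, h = octahedral_spring
        assignment = assign_types(geom, topo)
        bonds, angles = all_metal_parameters(h, geom, topo, assignment)
        assert len(bonds) == 6 and len(angles) == 15
        assert all(p.involves_metal for p in bonds + angles)

    def test_no_metal_fragment_tags_false(self):
        g = MolecularGeometry(
            elements=["C", "C", "H"],
            coordinates=[[0, 0, 0], [1.54, 0, 0], [1.9, 1.0, 0]])
        topo = build_topology(g, require_metal=False)
        model = SpringModel.uniform(g, topo)
        h = make_spring_hessian(model)
        from metalff import assign_base_types
        bonds, angles = all_metal_parameters(h, g, topo,
                                             assign_base_types(g, topo))
        assert all(not p.involves_metal for p in bonds + angles)

    def test_mixed_complex_tag_is_metal_membership(self, tris_bidentate):
        geom, topo = tris_bidentate
        h = make_spring_hessian(SpringModel.uniform(geom, topo))
        bonds, angles = all_metal_parameters(
            h, geom, topo, assign_types(geom, topo))
        for p in bonds + angles:
            assert p.involves_metal == bool(set(p.atoms) & topo.metal_indices)
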