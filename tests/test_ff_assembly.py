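"""Database lookup, hybrid merging, and UFF-derived metal LJ terms."""

import numpy as np
import pytest

from metalff import (assemble, assign_types, default_database,
                     load_parameter_database, metal_lj)
from metalff.ff_assembly import (DatabaseParseError, ParameterDatabase,
                                 Provenance)
from metalff._elements import UFF_LJ
from metalff.fixtures import SpringModel, make_ideal_complex, \
    make_spring_hessian
from metalff.seminario import all_metal_parameters


MINI_FRCMOD = """test database
BOND
ca-ca  478.40  1.387

ANGLE
ca-ca-ca  67.20  119.97

NONBON
  ca  1.9080  0.0860
"""


class TestDatabase:
    def test_bond_lookup(self):
        db = load_parameter_database(MINI_FRCMOD)
        assert db.lookup_bond("ca", "ca") == (478.40, 1.387)

    def test_reversed_tuple_identical(self):
        db = load_parameter_database(
            MINI_FRCMOD.replace("ca-ca  478", "ca-cb  478"))
        assert db.lookup_bond("ca", "cb") == db.lookup_bond("cb", "ca")

    def test_absent_key_is_miss_not_error(self):
        db = load_parameter_database(MINI_FRCMOD)
        assert db.lookup_bond("zz", "zz") is None

    def test_malformed_line_names_location(self):
        with pytest.raises(DatabaseParseError, match="line 3"):
            load_parameter_database("bad db\nBOND\nca+ğ 478\n")

    def test_wildcard_dihedral_lookup(self):
        db = default_database()
        assert db.lookup_dihedral("ha", "ca", "ca", "ha") is not None

    def test_embedded_fallback_has_common_organics(self):
        db = default_database()
        assert db.lookup_bond("ca", "ha") is not None
        assert db.lookup_angle("ca", "ca", "ca") is not None


class TestMetalLj:
    @pytest.mark.parametrize("element", ["Ru", "Fe", "Hg", "Pd"])
    def test_halving_rule(self, element):
        entry = metal_lj(element)
        x, d = UFF_LJ[element]
        assert entry.r_min_half == x / 2.0
        assert entry.epsilon == d

    def test_unknown_element_suggests_manual_entry(self):
        with pytest.raises(KeyError, match="manual"):
            metal_lj("Zz" if "Zz" in UFF_LJ else "Xe")


@pytest.fixture
def assembled(tris_bidentate):
    geom, topo = tris_bidentate
    h = make_spring_hessian(SpringModel.uniform(geom, topo))
    assignment = assign_types(geom, topo)
    bonds, angles = all_metal_parameters(h, geom, topo, assignment)
    params = assemble(topo, assignment, bonds, angles, default_database(),
                      elements=geom.elements)
    return geom, topo, assignment, params


class TestAssemble:
    def test_metal_terms_are_seminario(self, assembled):
        geom, topo, assignment, params = assembled
        metal_type = assignment.types[0]
        for key, entry in params.bonds.items():
            if metal_type in key:
                assert entry.provenance is Provenance.SEMINARIO
        for key, entry in params.angles.items():
            if metal_type in key:
                assert entry.provenance is Provenance.SEMINARIO

    def test_metal_dihedrals_zeroed(self, assembled):
        geom, topo, assignment, params = assembled
        metal_type = assignment.types[0]
        zeroed = [e for k, e in params.dihedrals.items() if metal_type in k]
        assert zeroed, "expected metal-involving dihedral keys"
        for entry in zeroed:
            assert entry.provenance is Provenance.ZEROED
            assert entry.terms[0].barrier == 0.0
            assert entry.terms[0].periodicity == 1
            assert entry.terms[0].phase == 0.0

    def test_empty_database_all_seminario(self, octahedral_spring):
        geom, topo, model, h = octahedral_spring
        assignment = assign_types(geom, topo)
        bonds, angles = all_metal_parameters(h, geom, topo, assignment)
        params = assemble(topo, assignment, bonds, angles, None,
                          elements=geom.elements)
        assert len(params.bonds) == 6 and len(params.angles) == 15
        for entry in list(params.bonds.values()) + list(params.angles.values()):
            assert entry.provenance is Provenance.SEMINARIO

    def test_database_hit_used_for_organic_term(self):
        geom, topo = make_ideal_complex("tris_bidentate")
        h = make_spring_hessian(SpringModel.uniform(geom, topo))
        assignment = assign_types(geom, topo)
        bonds, angles = all_metal_parameters(h, geom, topo, assignment)
        db = load_parameter_database(
            "t\nBOND\nc2-c2  300.00  1.697\n")
        params = assemble(topo, assignment, bonds, angles, db,
                          elements=geom.elements)
        entry = params.bonds[("c2", "c2")]
        assert entry.provenance is Provenance.DATABASE
        assert entry.k == 300.0

    def test_database_miss_falls_back_to_seminario(self, assembled):
        geom, topo, assignment, params = assembled
        # N-C backbone bonds are not in the embedded organic table
        entry = params.bonds[("N1", "c2")]
        assert entry.provenance is Provenance.SEMINARIO
        assert ("N1", "c2") in params.missing_in_database

    def test_coverage_no_shortage_no_duplication(self, assembled):
        from metalff import parameter_key
        geom, topo, assignment, params = assembled
        bond_keys = {parameter_key(b, assignment) for b in topo.bonds}
        angle_keys = {parameter_key(a, assignment) for a in topo.angles}
        dihe_keys = {parameter_key(d, assignment) for d in topo.dihedrals}
        assert set(params.bonds) == bond_keys
        assert set(params.angles) == angle_keys
        assert set(params.dihedrals) == dihe_keys

    def test_provenance_partition_disjoint(self, assembled):
        *_, params = assembled
        counts = params.provenance_counts()
        n_entries = (len(params.bonds) + len(params.angles)
                     + len(params.dihedrals) + len(params.lj))
        assert sum(counts.values()) == n_entries

    def test_metal_lj_attached_with_uff_provenance(self, assembled):
        geom, topo, assignment, params = assembled
        entry = params.lj[assignment.types[0]]
        assert entry.source.startswith("UFF")
        x, d = UFF_LJ[geom.elements[0]]
        assert entry.r_min_half == x / 2.0

    def test_determinism(self, tris_bidentate):
        geom, topo = tris_bidentate
        h = make_spring_hessian(SpringModel.uniform(geom, topo))
        snapshots = []
        for _ in range(2):
            assignment = assign_types(geom, topo)
            bonds, angles = all_metal_parameters(h, geom, topo, assignment)
            params = assemble(topo, assignment, bonds, angles,
                              default_database(), elements=geom.elements)
            snapshots.append((
                sorted(params.bonds.items(), key=lambda kv: kv[0]),
                sorted((k, v.k_theta, v.theta_eq)
                       for k, v in params.angles.items()),
            ))
        assert repr(snapshots[0]) == repr(snapshots[1])
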