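"""Structure parsing, contact geometry, interfaces, SASA and core/rim."""

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_interchain_pairs
from sf3bcons.structure import (
    Atom,
    Chain,
    ComplexStructure,
    ContactParams,
    MappingConflictError,
    Residue,
    classify_overlap,
    core_rim,
    find_contacts,
    interface_sets,
    label_core_rim,
    percent_interface,
    read_structure,
    relative_sasa,
    sasa,
    union_interfaces,
    write_pdb,
)
from sf3bcons.synthetic import simulate_complex


def two_atom_structure(distance: float) -> ComplexStructure:
    return ComplexStructure(
        "two",
        [
            Chain("A", "P1", "protein",
                  [Residue(1, "", "GLY", [Atom("CA", "C", np.zeros(3))])]),
            Chain("B", "P2", "protein",
                  [Residue(1, "", "GLY", [Atom("CA", "C", np.array([distance, 0.0, 0.0]))])]),
        ],
    )


class TestReadWriteStructure:
    def test_pdb_round_trip_counts(self, tmp_path):
        truth = simulate_complex(
            [("P1", "protein", 8), ("P2", "protein", 6)], 3, seed=4
        )
        path = tmp_path / "toy.pdb"
        write_pdb(truth.structure, path)
        st = read_structure(
            path, {"A": ("P1", "protein"), "B": ("P2", "protein")}
        )
        assert [len(c.residues) for c in st.chains] == [8, 6]

    def test_absent_chain_named_in_error(self, tmp_path):
        truth = simulate_complex([("P1", "protein", 4), ("P2", "protein", 4)], 0, seed=0)
        path = tmp_path / "toy.pdb"
        write_pdb(truth.structure, path)
        with pytest.raises(KeyError, match="Z"):
            read_structure(path, {"A": ("P1", "protein"), "Z": ("P9", "protein")})

    def test_unmapped_chain_warns(self, tmp_path):
        truth = simulate_complex([("P1", "protein", 4), ("P2", "protein", 4)], 0, seed=0)
        path = tmp_path / "toy.pdb"
        write_pdb(truth.structure, path)
        with pytest.warns(UserWarning, match="unmapped"):
            st = read_structure(path, {"A": ("P1", "protein")})
        assert len(st.chains) == 1

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  ALA B   1      50.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(pdb)
        st = read_structure(path, {"A": ("P1", "protein"), "B": ("P2", "protein")})
        res = st.chain("A").residues[0]
        assert len(res.atoms) == 1
        assert res.atoms[0].coord[0] == pytest.approx(1.0)

    def test_waters_and_hydrogens_dropped(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       0.500   0.000   0.000  1.00  0.00           H\n"
            "HETATM    3  O   HOH A   2       9.000   0.000   0.000  1.00  0.00           O\n"
            "ATOM      4  CA  ALA B   1      50.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "w.pdb"
        path.write_text(pdb)
        st = read_structure(path, {"A": ("P1", "protein"), "B": ("P2", "protein")})
        assert len(st.chain("A").residues) == 1
        assert [a.name for a in st.chain("A").residues[0].atoms] == ["CA"]


class TestFindContacts:
    def test_pair_inside_cutoff_detected(self):
        recs = find_contacts(two_atom_structure(4.9))
        assert any(r.interaction_type == "generic" for r in recs)

    def test_pair_outside_cutoff_ignored(self):
        assert find_contacts(two_atom_structure(5.1)) == []

    def test_planted_contacts_recovered_exactly(self):
        truth = simulate_complex(
            [("P1", "protein", 20), ("P2", "protein", 20)], 5, seed=1
        )
        recs = find_contacts(truth.structure)
        got = {(r.chain_a, r.residue_a[0], r.chain_b, r.residue_b[0]) for r in recs}
        want = {(a, ra, b, rb) for a, ra, b, rb, _ in truth.planted_contacts}
        assert got == want

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        truth = simulate_complex(
            [("P1", "protein", 15), ("P2", "protein", 12), ("R", "RNA", 8)],
            5,
            seed=seed,
            sidechains=(seed % 2 == 0),
        )
        recs = find_contacts(truth.structure)
        got = {(r.chain_a, r.residue_a[0], r.chain_b, r.residue_b[0]) for r in recs}
        assert got == oracle_interchain_pairs(truth.structure, 5.0)

    def test_residue_pair_relation_symmetric_under_chain_reorder(self):
        truth = simulate_complex([("P1", "protein", 10), ("P2", "protein", 10)], 3, seed=2)
        st = truth.structure
        flipped = ComplexStructure(st.structure_id, list(reversed(st.chains)))
        as_pairs = lambda recs: {
            frozenset([(r.chain_a, r.residue_a), (r.chain_b, r.residue_b)]) for r in recs
        }
        assert as_pairs(find_contacts(st)) == as_pairs(find_contacts(flipped))

    def test_interaction_subtypes_on_constructed_atoms(self):
        # Ser OG vs Ser OG at 3.0 A: generic + hbond; Asp OD1 vs Lys NZ at
        # 5.5 A: ionic only; Leu CD1 vs Leu CD1 at 4.5 A: generic + hydrophobic
        def chain(cid, comp, resname, atom, elem, x):
            return Chain(cid, comp, "protein",
                         [Residue(1, "", resname, [Atom(atom, elem, np.array([x, 0.0, 0.0]))])])

        st = ComplexStructure("t", [chain("A", "P1", "SER", "OG", "O", 0.0),
                                    chain("B", "P2", "SER", "OG", "O", 3.0)])
        assert {r.interaction_type for r in find_contacts(st)} == {"generic", "hbond"}
        st = ComplexStructure("t", [chain("A", "P1", "ASP", "OD1", "O", 0.0),
                                    chain("B", "P2", "LYS", "NZ", "N", 5.5)])
        assert {r.interaction_type for r in find_contacts(st)} == {"ionic"}
        st = ComplexStructure("t", [chain("A", "P1", "LEU", "CD1", "C", 0.0),
                                    chain("B", "P2", "LEU", "CD1", "C", 4.5)])
        assert {r.interaction_type for r in find_contacts(st)} == {"generic", "hydrophobic"}

    def test_single_chain_rejected(self):
        st = two_atom_structure(4.0)
        st.chains = st.chains[:1]
        with pytest.raises(ValueError):
            find_contacts(st)


class TestInterfaceSets:
    def test_two_ordered_sets_per_touching_pair(self):
        recs = find_contacts(two_atom_structure(4.0))
        sets = interface_sets(recs)
        assert [(s.owner, s.partner) for s in sets] == [("P1", "P2"), ("P2", "P1")]

    def test_empty_contacts_empty_result(self):
        assert interface_sets([]) == []

    def test_three_components_pairwise_touching_six_sets(self):
        st = ComplexStructure(
            "tri",
            [
                Chain("A", "P1", "protein",
                      [Residue(1, "", "GLY", [Atom("CA", "C", np.array([0.0, 0, 0]))])]),
                Chain("B", "P2", "protein",
                      [Residue(1, "", "GLY", [Atom("CA", "C", np.array([4.0, 0, 0]))])]),
                Chain("C", "P3", "protein",
                      [Residue(1, "", "GLY", [Atom("CA", "C", np.array([2.0, 3.2, 0]))])]),
            ],
        )
        sets = interface_sets(find_contacts(st))
        assert len(sets) == 6

    def test_residue_listed_once_despite_multiplicity(self):
        truth = simulate_complex([("P1", "protein", 10), ("P2", "protein", 10)], 4, seed=3)
        sets = interface_sets(find_contacts(truth.structure))
        for s in sets:
            assert s.size == len(set(s.residues))


class TestUnionInterfaces:
    def make_set(self, owner, partner, chain, numbers):
        from sf3bcons.structure import InterfaceSet, ResidueEvidence

        s = InterfaceSet(owner=owner, partner=partner)
        for n in numbers:
            s.residues[(chain, n, "")] = ResidueEvidence()
        return s

    def mapping(self, rows):
        return pd.DataFrame(
            rows,
            columns=["structure_id", "chain_id", "residue_number", "reference_position"],
        )

    def test_union_of_identical_sets_keeps_provenance(self):
        s1 = self.make_set("P1", "P2", "A", [1, 2, 3])
        s2 = self.make_set("P1", "P2", "A", [1, 2, 3])
        m = self.mapping(
            [(sid, "A", n, n + 100) for sid in ("st1", "st2") for n in (1, 2, 3)]
        )
        u = union_interfaces([("st1", s1), ("st2", s2)], m)
        assert sorted(u.residues) == [101, 102, 103]
        assert all(ev.structures == {"st1", "st2"} for ev in u.residues.values())

    def test_disjoint_sets_sizes_add(self):
        s1 = self.make_set("P1", "P2", "A", [1, 2, 3])
        s2 = self.make_set("P1", "P2", "A", [4, 5, 6, 7])
        m = self.mapping([("st1", "A", n, n) for n in (1, 2, 3)]
                         + [("st2", "A", n, n) for n in (4, 5, 6, 7)])
        u = union_interfaces([("st1", s1), ("st2", s2)], m)
        assert u.size == 7

    def test_cross_species_numbering_hand_fixture(self):
        # yeast-numbered {10, 11, 12} and human-numbered {205, 206} map to
        # reference positions {1..4}: 12 and 205 are the same position 3
        yeast = self.make_set("P1", "P2", "Y", [10, 11, 12])
        human = self.make_set("P1", "P2", "H", [205, 206])
        m = self.mapping(
            [
                ("y", "Y", 10, 1), ("y", "Y", 11, 2), ("y", "Y", 12, 3),
                ("h", "H", 205, 3), ("h", "H", 206, 4),
            ]
        )
        u = union_interfaces([("y", yeast), ("h", human)], m)
        assert sorted(u.residues) == [1, 2, 3, 4]
        assert u.residues[3].structures == {"y", "h"}

    def test_unmapped_residues_reported_not_dropped(self):
        s1 = self.make_set("P1", "P2", "A", [1, 2])
        m = self.mapping([("st1", "A", 1, 1)])
        u = union_interfaces([("st1", s1)], m)
        assert u.size == 1
        assert u.unmapped == [("st1", ("A", 2, ""))]

    def test_conflicting_mapping_raises(self):
        s1 = self.make_set("P1", "P2", "A", [1])
        m = self.mapping([("st1", "A", 1, 1), ("st1", "A", 1, 2)])
        with pytest.raises(MappingConflictError):
            union_interfaces([("st1", s1)], m)

    def test_mixed_component_pairs_rejected(self):
        s1 = self.make_set("P1", "P2", "A", [1])
        s2 = self.make_set("P1", "P3", "A", [1])
        with pytest.raises(ValueError):
            union_interfaces([("a", s1), ("b", s2)], self.mapping([]))


class TestPercentInterfaceAndOverlap:
    def test_percent_simple(self):
        s = TestUnionInterfaces().make_set("P1", "P2", "A", range(1, 11))
        assert percent_interface("P1", [s], 100) == 10.0

    def test_shared_residue_counts_once(self):
        t = TestUnionInterfaces()
        s1 = t.make_set("P1", "P2", "A", [1, 2])
        s2 = t.make_set("P1", "P3", "A", [2, 3])
        assert percent_interface("P1", [s1, s2], 10) == 30.0

    def test_no_interfaces_zero(self):
        assert percent_interface("P1", [], 50) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_interface("P1", [], 0)

    def test_percent_monotone_in_partners(self):
        t = TestUnionInterfaces()
        s1 = t.make_set("P1", "P2", "A", [1, 2])
        s2 = t.make_set("P1", "P3", "A", [3])
        assert percent_interface("P1", [s1], 10) <= percent_interface("P1", [s1, s2], 10)

    def test_overlap_classification(self):
        t = TestUnionInterfaces()
        s1 = t.make_set("SF3b1", "X", "A", [1, 2])
        s2 = t.make_set("SF3b1", "Y", "A", [2, 3])
        cls = classify_overlap("SF3b1", [s1, s2])
        assert cls[("A", 2, "")] == "overlapping"
        assert cls[("A", 1, "")] == "non_overlapping"

    def test_single_partner_all_non_overlapping(self):
        t = TestUnionInterfaces()
        s1 = t.make_set("P1", "P2", "A", [1, 2, 3])
        assert set(classify_overlap("P1", [s1]).values()) == {"non_overlapping"}


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        st = two_atom_structure(100.0)
        areas = sasa(st)
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert areas[("A", 1, "")] == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_independent(self):
        st = two_atom_structure(100.0)
        areas = sasa(st)
        assert areas[("A", 1, "")] == pytest.approx(areas[("B", 1, "")], rel=1e-9)

    def test_caged_atom_buried(self):
        # central carbon enclosed by a dense shell of carbons at 3.0 A
        shell_pts = []
        n = 100
        golden = (1 + 5 ** 0.5) / 2
        for i in range(n):
            z = 1 - (2 * i + 1) / n
            theta = 2 * np.pi * i / golden
            r = np.sqrt(1 - z * z)
            shell_pts.append(3.0 * np.array([r * np.cos(theta), r * np.sin(theta), z]))
        center = Chain("A", "P1", "protein",
                       [Residue(1, "", "GLY", [Atom("CA", "C", np.zeros(3))])])
        cage = Chain("B", "P2", "protein",
                     [Residue(i + 1, "", "GLY", [Atom("CA", "C", p)])
                      for i, p in enumerate(shell_pts)])
        areas = sasa(ComplexStructure("cage", [center, cage]))
        assert areas[("A", 1, "")] == pytest.approx(0.0, abs=1e-9)

    def test_distant_chain_limit_bound_equals_unbound(self):
        truth = simulate_complex([("P1", "protein", 8), ("P2", "protein", 8)], 0, seed=9)
        st = truth.structure
        unbound = sasa(st, chains=["A"])
        bound = sasa(st)  # chains already > 50 A apart with zero contacts
        for key, area in unbound.items():
            assert abs(bound[key] - area) < 1e-6

    def test_cross_check_against_biotite(self):
        # independent Shrake-Rupley implementation on a small random cloud
        biotite_struct = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 8, size=(12, 3))
        chain = Chain("A", "P", "protein",
                      [Residue(i + 1, "", "GLY", [Atom("CA", "C", c)])
                       for i, c in enumerate(coords)])
        chain_b = Chain("B", "Q", "protein",
                        [Residue(1, "", "GLY", [Atom("CA", "C", np.array([200.0, 0, 0]))])])
        ours = sasa(ComplexStructure("x", [chain, chain_b]), n_points=5000)
        arr = biotite_struct.AtomArray(13)
        arr.coord = np.vstack([coords, [[200.0, 0, 0]]]).astype(np.float32)
        arr.chain_id = ["A"] * 12 + ["B"]
        arr.res_id = list(range(1, 13)) + [1]
        arr.res_name = ["GLY"] * 13
        arr.atom_name = ["CA"] * 13
        arr.element = ["C"] * 13
        ref = biotite_struct.sasa(arr, point_number=5000, vdw_radii="Single")
        for i in range(12):
            assert ours[("A", i + 1, "")] == pytest.approx(float(ref[i]), rel=0.05, abs=1.0)


class TestCoreRim:
    @pytest.mark.parametrize(
        "unbound,bound,expected",
        [(45.0, 2.0, "core"), (45.0, 8.5, "rim"), (45.0, 30.0, "other"),
         (5.0, 2.0, "other")],  # buried before binding: never core
    )
    def test_threshold_rule(self, unbound, bound, expected):
        assert label_core_rim(unbound, bound) == expected

    def test_relative_sasa_unknown_residue_warns(self):
        with pytest.warns(UserWarning):
            relative_sasa(50.0, "XYZ")

    def test_end_to_end_on_toy_complex(self):
        truth = simulate_complex([("P1", "protein", 10), ("P2", "protein", 10)], 3, seed=5)
        labels = core_rim(truth.structure, ("P1", "P2"))
        iface = {(a, ra) for a, ra, b, rb, _ in truth.planted_contacts} | {
            (b, rb) for a, ra, b, rb, _ in truth.planted_contacts
        }
        owner_iface = {k for k in iface if k[0] == "A"}
        assert {(l.residue[0], l.residue[1]) for l in labels} == owner_iface
        for l in labels:
            assert 0.0 <= l.rsasa_bound <= l.rsasa_unbound + 1e-9
            assert l.label in {"core", "rim", "other"}
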