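"""Buried-surface bookkeeping: totals, decomposition, residues, bridges."""

import numpy as np
import pandas as pd
import pytest

from cadkit.interface import (
    BIOLOGICAL,
    CRYSTAL,
    BuriedSurface,
    InterfaceParams,
    analyze_interface,
    buried_surface,
    classify_interface,
    composition,
    detect_salt_bridges,
    interface_area,
    interface_residues,
    repeat_pair_areas,
)
from cadkit.sasa import SASAParams, compute_sasa
from cadkit.structures import (
    AtomRecord,
    AtomSelection,
    Structure,
    StructureError,
    select_atoms,
)
from cadkit.synthetic import make_toy_dimer, two_sphere_areas


def _atom(serial, name, element, resname, chain, num, pos):
    return AtomRecord(serial, name, element, resname, chain, num, "", pos)


class TestBuriedSurface:
    def test_far_apart_protomers_bury_nothing(self, tmp_path):
        bundle = make_toy_dimer(str(tmp_path), n_repeats=1, residues_per_repeat=4, gap=100.0)
        from cadkit.structures import read_structure

        s = read_structure(bundle.files["dimer"])
        b = buried_surface(s, {"A"}, {"B"})
        assert b.table["bsa"].max() == pytest.approx(0.0, abs=1e-6)
        assert interface_area(b) == pytest.approx(0.0, abs=1e-6)

    def test_burial_is_local_to_the_contacting_residues(self, single_contact_dimer):
        bundle, structure, annotations = single_contact_dimer
        b = buried_surface(structure, {"A"}, {"B"}, annotations=annotations)
        buried = b.table[b.table["bsa"] > 1.0]
        got = {(r.chain, r.residue_number) for r in buried.itertuples()}
        expected = {("A", i) for i, _ in bundle.truth["contact_pairs"]}
        expected |= {("B", j) for _, j in bundle.truth["contact_pairs"]}
        assert got == expected

    def test_two_sphere_chains_match_cap_formula(self):
        atoms = [
            _atom(1, "C", "C", "GLY", "A", 1, (0.0, 0.0, 0.0)),
            _atom(2, "C", "C", "GLY", "B", 1, (2.0, 0.0, 0.0)),
        ]
        s = Structure(atoms=atoms)
        b = buried_surface(s, {"A"}, {"B"})
        free = 4 * np.pi * 3.1**2
        a1, _ = two_sphere_areas(1.7, 1.7, 2.0)
        expected_bsa = free - a1
        got = b.table.set_index("chain")["bsa"]
        assert got["A"] == pytest.approx(expected_bsa, rel=0.02)
        assert got["B"] == pytest.approx(expected_bsa, rel=0.02)

    def test_overlapping_chain_sets_rejected(self, toy_dimer):
        _, structure, _ = toy_dimer
        with pytest.raises(StructureError, match="overlap"):
            buried_surface(structure, {"A"}, {"A", "B"})

    def test_brute_force_three_way_subtraction(self, single_contact_dimer):
        """Module BSA equals an independent three-SASA subtraction."""
        _, structure, _ = single_contact_dimer
        b = buried_surface(structure, {"A"}, {"B"})
        params = SASAParams()
        free_a = compute_sasa(select_atoms(structure, AtomSelection(chains={"A"})), params)
        bound = compute_sasa(structure, params)
        for key, asa_free in free_a.per_residue_area.items():
            expected = max(0.0, asa_free - bound.per_residue_area.get(key, 0.0))
            row = b.table[
                (b.table["chain"] == key[0]) & (b.table["residue_number"] == key[1])
            ]
            assert float(row["bsa"].iloc[0]) == pytest.approx(expected, abs=1e-9)


class TestDecomposition:
    def test_single_contact_gives_single_pair(self, single_contact_dimer):
        bundle, structure, annotations = single_contact_dimer
        b = buried_surface(structure, {"A"}, {"B"}, annotations=annotations)
        pairs = repeat_pair_areas(b)
        assert set(pairs) == set(bundle.truth["repeat_pairs"])

    def test_full_overlap_antiparallel_register(self, toy_dimer):
        bundle, structure, annotations = toy_dimer
        b = buried_surface(structure, {"A"}, {"B"}, annotations=annotations)
        pairs = repeat_pair_areas(b)
        assert set(pairs) == {"R1:R4", "R2:R3", "R3:R2", "R4:R1"}
        assert all(v > 0 for v in pairs.values())

    def test_pairs_plus_other_conserve_total(self, toy_dimer):
        _, structure, annotations = toy_dimer
        b = buried_surface(structure, {"A"}, {"B"}, annotations=annotations)
        pairs = repeat_pair_areas(b)
        assert sum(pairs.values()) == pytest.approx(interface_area(b), abs=1e-3)

    def test_unannotated_burial_lands_in_other(self, toy_dimer):
        _, structure, _ = toy_dimer
        b = buried_surface(structure, {"A"}, {"B"}, annotations=None)
        pairs = repeat_pair_areas(b)
        assert set(pairs) == {"other"}
        assert pairs["other"] == pytest.approx(interface_area(b), abs=1e-3)

    def test_symmetric_dimer_buries_equally(self, toy_dimer):
        _, structure, _ = toy_dimer
        b = buried_surface(structure, {"A"}, {"B"})
        burial_a = b.protomer("A")["bsa"].sum()
        burial_b = b.protomer("B")["bsa"].sum()
        assert burial_a == pytest.approx(burial_b, rel=0.02)
        # swapping the protomer roles cannot change the interface area
        b_swapped = buried_surface(structure, {"B"}, {"A"})
        assert interface_area(b_swapped) == pytest.approx(interface_area(b), abs=1e-9)


class TestInterfaceResidues:
    def _table(self, rows):
        cols = [
            "protomer", "chain", "residue_number", "insertion_code", "residue_name",
            "repeat_label", "asa_free", "asa_complex", "bsa", "partner_repeat_label",
        ]
        return BuriedSurface(pd.DataFrame(rows, columns=cols), frozenset("A"), frozenset("B"))

    def test_threshold_is_inclusive_at_the_boundary(self):
        b = self._table(
            [
                ("A", "A", 1, "", "LYS", "R1", 100.0, 75.0, 25.0, "R2"),
                ("A", "A", 2, "", "GLU", "R1", 100.0, 81.0, 19.0, "R2"),
                ("A", "A", 3, "", "SER", "R1", 0.0, 0.0, 0.0, ""),
            ]
        )
        out = interface_residues(b, 0.20)
        assert list(out["residue_number"]) == [1]
        assert out["bsa_fraction"].iloc[0] == pytest.approx(0.25)

    def test_zero_asa_residue_never_qualifies(self):
        b = self._table([("A", "A", 1, "", "GLY", "R1", 0.0, 0.0, 0.0, "")])
        assert len(interface_residues(b, 0.01)) == 0

    def test_raising_threshold_never_adds_residues(self, toy_dimer):
        _, structure, _ = toy_dimer
        b = buried_surface(structure, {"A"}, {"B"})
        previous = None
        for thr in (0.05, 0.2, 0.5, 0.9):
            current = set(
                map(tuple, interface_residues(b, thr)[["chain", "residue_number"]].values)
            )
            if previous is not None:
                assert current <= previous
            previous = current


class TestComposition:
    def test_all_leucine_interface_is_fully_hydrophobic(self, toy_dimer):
        _, structure, _ = toy_dimer  # built from LEU residues
        b = buried_surface(structure, {"A"}, {"B"})
        comp = composition(b)
        assert comp["hydrophobic"] == pytest.approx(1.0)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-6)

    def test_unmapped_residue_is_reported(self, toy_dimer):
        _, structure, _ = toy_dimer
        b = buried_surface(structure, {"A"}, {"B"})
        with pytest.raises(StructureError, match="LEU"):
            composition(b, class_map={"ALA": "hydrophobic"})

    def test_fractions_sum_to_one_for_mixed_classes(self, tmp_path):
        bundle = make_toy_dimer(str(tmp_path), n_repeats=2, residues_per_repeat=4,
                                residue_name="LYS")
        from cadkit.structures import read_structure

        b = buried_surface(read_structure(bundle.files["dimer"]), {"A"}, {"B"})
        comp = composition(b)
        assert comp["charged"] == pytest.approx(1.0)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-6)


class TestSaltBridges:
    def _pair(self, distance):
        atoms = [
            _atom(1, "CA", "C", "LYS", "A", 10, (0.0, 0.0, 0.0)),
            _atom(2, "NZ", "N", "LYS", "A", 10, (0.0, 0.0, 2.0)),
            _atom(3, "CA", "C", "GLU", "B", 40, (0.0, distance + 4.0, 0.0)),
            _atom(4, "OE1", "O", "GLU", "B", 40, (0.0, distance, 2.0)),
        ]
        return Structure(atoms=atoms)

    def test_lys_glu_pair_within_cutoff(self):
        bridges = detect_salt_bridges(self._pair(3.0), {"A"}, {"B"}, cutoff=4.0)
        assert len(bridges) == 1
        br = bridges[0]
        assert br.residue_a == ("A", 10, "LYS") and br.residue_b == ("B", 40, "GLU")
        assert br.atom_a == "NZ" and br.atom_b == "OE1"
        assert br.distance == pytest.approx(3.0)

    def test_pair_beyond_cutoff_excluded(self):
        assert detect_salt_bridges(self._pair(4.5), {"A"}, {"B"}, cutoff=4.0) == []

    def test_histidine_only_when_enabled(self):
        atoms = [
            _atom(1, "NE2", "N", "HIS", "A", 5, (0.0, 0.0, 0.0)),
            _atom(2, "OD1", "O", "ASP", "B", 9, (3.0, 0.0, 0.0)),
        ]
        s = Structure(atoms=atoms)
        assert detect_salt_bridges(s, {"A"}, {"B"}) == []
        assert len(detect_salt_bridges(s, {"A"}, {"B"}, include_histidine=True)) == 1

    def test_intra_protomer_pairs_ignored(self):
        atoms = [
            _atom(1, "NZ", "N", "LYS", "A", 1, (0.0, 0.0, 0.0)),
            _atom(2, "OE1", "O", "GLU", "A", 2, (3.0, 0.0, 0.0)),
            _atom(3, "CA", "C", "GLY", "B", 1, (50.0, 0.0, 0.0)),
        ]
        assert detect_salt_bridges(Structure(atoms=atoms), {"A"}, {"B"}) == []


class TestClassification:
    @pytest.mark.parametrize(
        "area,expected",
        [(1539.0, BIOLOGICAL), (1270.0, BIOLOGICAL), (100.0, CRYSTAL), (856.0, CRYSTAL)],
    )
    def test_empirical_cutoff_with_strict_inequality(self, area, expected):
        assert classify_interface(area, 856.0) == expected

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            classify_interface(-1.0)


class TestFullAnalysis:
    def test_analyze_interface_report_is_consistent(self, toy_dimer):
        _, structure, annotations = toy_dimer
        rep = analyze_interface(structure, {"A"}, {"B"}, annotations=annotations)
        assert rep.total_area > 0
        assert sum(rep.per_pair_area.values()) == pytest.approx(rep.total_area, abs=1e-3)
        assert rep.classification in (BIOLOGICAL, CRYSTAL)
        for comp in rep.composition_per_pair.values():
            assert sum(comp.values()) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            InterfaceParams(residue_fraction_threshold=0.0)
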