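"""Contacts, salt bridges, anchor identification and spacing arithmetic."""

import numpy as np
import pytest

from cambind.binding_interface import (
    Anchor,
    find_salt_bridges,
    heavy_atom_contacts,
    identify_anchors,
    spacing_pattern,
)
from cambind.domain_symmetry import DomainSpec
from cambind.errors import SelectionError
from cambind.structure_io import Atom, Residue, SelectionSpec

from conftest import brute_force_contacts, brute_force_salt_bridges

DOMS = (DomainSpec("R", (1, 30), "N-domain"), DomainSpec("R", (101, 130), "C-domain"))
PEPTIDE = SelectionSpec("P", (1, 24))


def _res(chain, num, name, atoms):
    return Residue(chain, num, name, [Atom(n, e, np.array(c, float))
                                      for n, e, c in atoms])


class TestHeavyAtomContacts:
    def test_single_pair_inside_and_outside_cutoff(self):
        model = [
            _res("P", 1, "ALA", [("CB", "C", (0, 0, 0))]),
            _res("R", 1, "ALA", [("CB", "C", (3.0, 0, 0))]),
        ]
        a = SelectionSpec("P", (1, 1))
        b = SelectionSpec("R", (1, 1))
        hits = heavy_atom_contacts(model, a, b, cutoff=4.5)
        assert len(hits) == 1
        assert hits[0].min_distance == pytest.approx(3.0)
        assert hits[0].n_atom_pairs == 1
        assert heavy_atom_contacts(model, a, b, cutoff=2.5) == []

    def test_matches_brute_force_all_pairs_oracle(self, toy_complex):
        model = toy_complex.models[0]
        rec = SelectionSpec("R", (1, 130))
        ours = {(c.peptide_residue, c.receptor_residue): (c.min_distance, c.n_atom_pairs)
                for c in heavy_atom_contacts(model, PEPTIDE, rec, cutoff=4.5)}
        oracle = brute_force_contacts(model, PEPTIDE, rec, cutoff=4.5)
        assert ours.keys() == oracle.keys()
        for key, (dmin, n_pairs) in oracle.items():
            assert ours[key][0] == pytest.approx(dmin, abs=1e-12)
            assert ours[key][1] == n_pairs

    def test_decreasing_cutoff_never_adds_contacts(self, toy_complex):
        model = toy_complex.models[0]
        rec = SelectionSpec("R", (1, 130))
        pairs = {}
        for cutoff in (6.0, 4.5, 3.5):
            found = {(c.peptide_residue, c.receptor_residue)
                     for c in heavy_atom_contacts(model, PEPTIDE, rec, cutoff)}
            if pairs:
                assert found <= pairs[max(pairs)]
            pairs[cutoff] = found

    def test_overlapping_groups_rejected(self, toy_complex):
        with pytest.raises(SelectionError):
            heavy_atom_contacts(toy_complex.models[0], PEPTIDE,
                                SelectionSpec("P", (20, 24)), 4.5)


class TestSaltBridges:
    @staticmethod
    def _arg_glu(distance):
        return [
            _res("P", 1, "ARG", [("CZ", "C", (0, 0, 0)),
                                 ("NH1", "N", (1.0, 0, 0)),
                                 ("NH2", "N", (0, 1.0, 0))]),
            _res("R", 5, "GLU", [("CD", "C", (1.0 + distance, 1.0, 0)),
                                 ("OE1", "O", (1.0 + distance, 0, 0)),
                                 ("OE2", "O", (1.0 + distance, 2.0, 0))]),
        ]

    def test_close_pair_found_far_pair_not(self):
        hits = find_salt_bridges(self._arg_glu(3.5), "P", "R")
        assert len(hits) == 1
        assert hits[0].min_NO_distance == pytest.approx(3.5)
        assert find_salt_bridges(self._arg_glu(6.0), "P", "R") == []

    def test_symmetric_in_chain_order(self):
        model = self._arg_glu(3.5)
        a = find_salt_bridges(model, "P", "R")
        b = find_salt_bridges(model, "R", "P")
        assert a == b

    def test_backbone_oxygen_does_not_count(self):
        model = [
            _res("P", 1, "ARG", [("NH1", "N", (0, 0, 0))]),
            _res("R", 5, "GLU", [("O", "O", (3.0, 0, 0))]),  # backbone O only
        ]
        assert find_salt_bridges(model, "P", "R") == []

    def test_matches_brute_force_oracle_on_constructed_cluster(self):
        rng = np.random.default_rng(9)
        model = []
        for i in range(6):
            base = rng.normal(0, 6, 3)
            model.append(_res("P", i + 1, "LYS",
                              [("NZ", "N", base), ("CE", "C", base + [1, 0, 0])]))
            model.append(_res("R", i + 1, "ASP",
                              [("OD1", "O", base + rng.normal(0, 3, 3)),
                               ("OD2", "O", base + rng.normal(0, 3, 3))]))
        ours = {(b.basic_residue, b.acidic_residue): b.min_NO_distance
                for b in find_salt_bridges(model, "P", "R")}
        assert ours == pytest.approx(brute_force_salt_bridges(model, "P", "R", 4.0))


class TestAnchors:
    def test_toy_complex_anchor_set_and_ranks(self, toy_complex):
        anchors = identify_anchors(toy_complex.models[0], PEPTIDE, DOMS)
        by_pos = {a.residue[1]: a for a in anchors}
        assert sorted(by_pos) == [1, 5, 15, 18]
        assert by_pos[1].rank == "major" and by_pos[18].rank == "major"
        assert by_pos[5].rank == "minor" and by_pos[15].rank == "minor"
        assert by_pos[1].buried_domain == "N-domain"
        assert by_pos[18].buried_domain == "C-domain"

    def test_polar_peptide_yields_no_anchors(self):
        model = [
            _res("P", i, "SER", [("CB", "C", (0, 0, float(i)))]) for i in range(1, 5)
        ] + [
            _res("R", 1, "LEU", [("CB", "C", (1.0, 0, 1.0))]),
        ]
        assert identify_anchors(model, SelectionSpec("P", (1, 4)), DOMS) == []

    def test_single_buried_ile_is_major(self):
        model = [_res("P", 1, "ILE", [("CB", "C", (0, 0, 0))])]
        for k in range(6):
            model.append(_res("R", k + 1, "LEU", [("CB", "C", (3.0, 0, k * 0.5))]))
        anchors = identify_anchors(model, SelectionSpec("P", (1, 1)), DOMS)
        assert len(anchors) == 1
        assert anchors[0].contact_count == 6
        assert anchors[0].rank == "major"


class TestSpacingPattern:
    @staticmethod
    def _anchor(num, domain="N-domain", chain="P"):
        return Anchor(residue=(chain, num, "ILE"), contact_count=3,
                      buried_domain=domain, rank="minor")

    def test_published_anchor_numbering_gives_1_5_15_18(self):
        anchors = [self._anchor(396), self._anchor(400),
                   self._anchor(410, "C-domain"), self._anchor(413, "C-domain")]
        pattern = spacing_pattern(anchors)
        assert pattern.indices == (1, 5, 15, 18)
        assert pattern.mode_label == "1–18"
        assert pattern.orientation == "parallel"

    def test_single_anchor_and_1_14_arithmetic(self):
        assert spacing_pattern([self._anchor(7)]).indices == (1,)
        pattern = spacing_pattern([self._anchor(3, "C-domain"), self._anchor(16)])
        assert pattern.mode_label == "1–14"
        assert pattern.orientation == "antiparallel"

    def test_renumbering_by_constant_leaves_indices_unchanged(self):
        base = [self._anchor(n) for n in (396, 400, 410, 413)]
        shifted = [self._anchor(n - 390) for n in (396, 400, 410, 413)]
        assert spacing_pattern(base).indices == spacing_pattern(shifted).indices

    def test_multiple_chains_rejected(self):
        with pytest.raises(SelectionError):
            spacing_pattern([self._anchor(1, chain="P"), self._anchor(5, chain="Q")])
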