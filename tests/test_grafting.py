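import io

import numpy as np
import pytest

from loopgraft import (
    Pairing,
    ResiduePair,
    Region,
    boundary_candidates,
    build_chimera,
    build_loops,
    combine,
    enumerate_designs,
    excised_scaffold_structure,
    insert_structures,
    load_chain,
    pair_structures,
    segment,
    write_pir,
)
from loopgraft.grafting import BoundaryCandidate, GraftWindow

from conftest import make_chain


def simple_loops(labels):
    return build_loops(segment(labels))


LABELS = "H" * 4 + "C" * 4 + "H" * 4  # one loop, indices 0..11


@pytest.fixture
def self_graft():
    rng = np.random.default_rng(0)
    coords = rng.normal(scale=4, size=(12, 3))
    chain = make_chain(coords, "ACDEFGHIKLMN")
    loop = simple_loops(LABELS)[0]
    pairing = Pairing.identity(12)
    return chain, loop, pairing


class TestBoundaryCandidates:
    def test_fully_paired_flanks_one_candidate_per_position(self, self_graft):
        chain, loop, pairing = self_graft
        n_list, c_list = boundary_candidates(
            loop, loop, pairing, chain.coords, chain.coords
        )
        assert len(n_list) == 4 and len(c_list) == 4
        assert all(c.distance == 0 and not c.from_gap for c in n_list)
        assert [(c.scaffold_index, c.insert_index) for c in n_list] == \
            [(k, k) for k in range(4)]

    def test_distal_to_proximal_order(self, self_graft):
        chain, loop, pairing = self_graft
        n_list, c_list = boundary_candidates(
            loop, loop, pairing, chain.coords, chain.coords
        )
        assert [c.scaffold_index for c in n_list] == [0, 1, 2, 3]
        assert [c.scaffold_index for c in c_list] == [11, 10, 9, 8]

    def test_gap_resolved_to_nearer_flanking_residue(self):
        # scaffold N flank residue 1 is unpaired; its anterior partner
        # lies 1.2 Å away and the posterior partner 2.5 Å away
        coords_s = np.zeros((12, 3))
        coords_s[:, 0] = np.arange(12) * 4.0
        coords_i = coords_s.copy()
        coords_i[0] = coords_s[1] + [1.2, 0.0, 0.0]
        coords_i[2] = coords_s[1] + [2.5, 0.0, 0.0]
        pairs = [ResiduePair(k, k, 0.5) for k in (0, 2, 3)] + \
            [ResiduePair(k, k, 0.5) for k in range(4, 12)]
        pairing = Pairing(pairs)
        loop = simple_loops(LABELS)[0]
        n_list, _ = boundary_candidates(loop, loop, pairing,
                                        coords_s, coords_i)
        # the unpaired scaffold residue resolves to the anterior partner
        # (1.2 Å) rather than the posterior one (2.5 Å); the unpaired
        # insert residue independently yields its own gap candidate
        gap = [c for c in n_list if c.from_gap
               and c.scaffold_index == 1]
        assert len(gap) == 1
        assert gap[0].insert_index == 0
        assert gap[0].distance == pytest.approx(1.2)

    def test_unpaired_flank_warns_and_empty(self, self_graft):
        chain, loop, _ = self_graft
        empty = Pairing([ResiduePair(k, k, 0.0) for k in range(8, 12)])
        with pytest.warns(UserWarning, match="not graftable"):
            n_list, c_list = boundary_candidates(
                loop, loop, empty, chain.coords, chain.coords
            )
        assert n_list == [] and len(c_list) == 4


class TestChimeraAssembly:
    def test_window_semantics_keep_boundary_residues(self):
        # scaffold ABCDEFGHIJ, insert abcdefghij (lower case stands in
        # for distinct letters); graft between boundaries 2 and 7
        scaffold = "ABCDEFGHIJ"
        insert = "QRSTUVWXYZ"
        w = GraftWindow(
            1,
            BoundaryCandidate(2, 2, "N", False, 0.0),
            BoundaryCandidate(7, 7, "C", False, 0.0),
        )
        seq, prov, segs = build_chimera(scaffold, insert, [w])
        assert seq == "ABC" + "TUVW" + "HIJ"
        assert segs == ["TUVW"]
        assert prov == ["scaffold"] * 3 + ["insert"] * 4 + ["scaffold"] * 3

    def test_inclusive_mode_takes_boundaries_from_insert(self):
        w = GraftWindow(
            1,
            BoundaryCandidate(2, 2, "N", False, 0.0),
            BoundaryCandidate(7, 7, "C", False, 0.0),
            inclusive=True,
        )
        seq, prov, _ = build_chimera("ABCDEFGHIJ", "QRSTUVWXYZ", [w])
        assert seq == "AB" + "STUVWX" + "IJ"

    def test_length_formula(self):
        w = GraftWindow(
            1,
            BoundaryCandidate(2, 1, "N", False, 0.0),
            BoundaryCandidate(7, 9, "C", False, 0.0),
        )
        seq, _, _ = build_chimera("ABCDEFGHIJ", "QRSTUVWXYZ", [w])
        excised, inserted = 7 - 2 - 1, 9 - 1 - 1
        assert len(seq) == 10 - excised + inserted

    def test_overlapping_windows_raise(self):
        w1 = GraftWindow(1, BoundaryCandidate(1, 1, "N", False, 0.0),
                         BoundaryCandidate(6, 6, "C", False, 0.0))
        w2 = GraftWindow(2, BoundaryCandidate(4, 4, "N", False, 0.0),
                         BoundaryCandidate(9, 9, "C", False, 0.0))
        with pytest.raises(ValueError, match="overlap"):
            build_chimera("ABCDEFGHIJ", "QRSTUVWXYZ", [w1, w2])


class TestEnumeration:
    def test_self_grafting_yields_no_novel_designs(self, self_graft):
        chain, loop, pairing = self_graft
        dset = enumerate_designs(loop, loop, pairing, chain, chain)
        assert len(dset) == 0

    def test_cross_product_with_distinct_sequences(self, divergent_pair):
        arch, scaffold, insert = divergent_pair
        pairing = pair_structures(scaffold, insert)
        loops = simple_loops(arch.labels)
        loop = loops[0]
        n_len = len(loop.n_flank.region)
        c_len = len(loop.c_flank.region)
        dset = enumerate_designs(loop, loop, pairing, scaffold, insert)
        assert len(dset) == n_len * c_len

    def test_combined_count_is_product(self, divergent_pair):
        arch, scaffold, insert = divergent_pair
        pairing = pair_structures(scaffold, insert)
        loops = simple_loops(arch.labels)
        # loops 1 and 3 do not share a flank, so windows never overlap
        sets = [
            enumerate_designs(lp, lp, pairing, scaffold, insert)
            for lp in (loops[0], loops[2])
        ]
        both = combine(sets, scaffold, insert)
        assert len(both) == len(sets[0]) * len(sets[1])

    def test_provenance_partitions_chimera(self, divergent_pair):
        arch, scaffold, insert = divergent_pair
        pairing = pair_structures(scaffold, insert)
        loop = simple_loops(arch.labels)[0]
        dset = enumerate_designs(loop, loop, pairing, scaffold, insert)
        for d in dset.designs:
            assert len(d.provenance) == len(d.chimera_sequence)
            scaffold_letters = [
                c for c, p in zip(d.chimera_sequence, d.provenance)
                if p == "scaffold"
            ]
            assert all(c in set(scaffold.sequence) for c in scaffold_letters)
            w = d.windows[0]
            expected_len = (len(scaffold)
                            - len(w.scaffold_removed)
                            + len(w.insert_kept))
            assert len(d.chimera_sequence) == expected_len

    def test_enumeration_is_deterministic(self, divergent_pair):
        arch, scaffold, insert = divergent_pair
        pairing = pair_structures(scaffold, insert)
        loop = simple_loops(arch.labels)[0]
        a = enumerate_designs(loop, loop, pairing, scaffold, insert)
        b = enumerate_designs(loop, loop, pairing, scaffold, insert)
        assert [d.chimera_sequence for d in a.designs] == \
            [d.chimera_sequence for d in b.designs]
        assert [d.design_id for d in a.designs] == \
            [d.design_id for d in b.designs]

    def test_combine_single_set_identity(self, self_graft):
        chain, loop, pairing = self_graft
        from loopgraft.grafting import DesignSet
        dset = DesignSet([])
        assert combine([dset], chain, chain) is dset


class TestPartialStructures:
    def test_excised_scaffold_residue_count(self):
        chain = make_chain(np.arange(150).reshape(50, 3), "A" * 50)
        w = GraftWindow(1, BoundaryCandidate(9, 9, "N", False, 0.0),
                        BoundaryCandidate(15, 15, "C", False, 0.0))
        text = excised_scaffold_structure(chain, [w])
        assert len(load_chain(text, "A")) == 50 - 5

    def test_no_windows_keeps_everything(self):
        chain = make_chain(np.arange(30).reshape(10, 3), "A" * 10)
        text = excised_scaffold_structure(chain, [])
        assert len(load_chain(text, "A")) == 10

    def test_one_insert_fragment_per_window(self):
        chain = make_chain(np.arange(90).reshape(30, 3), "A" * 30)
        windows = [
            GraftWindow(1, BoundaryCandidate(2, 2, "N", False, 0.0),
                        BoundaryCandidate(8, 8, "C", False, 0.0)),
            GraftWindow(2, BoundaryCandidate(15, 15, "N", False, 0.0),
                        BoundaryCandidate(25, 25, "C", False, 0.0)),
        ]
        texts = insert_structures(chain, windows)
        assert len(texts) == 2
        assert len(load_chain(texts[0], "A")) == 5
        assert len(load_chain(texts[1], "A")) == 9
        assert insert_structures(chain, []) == []


class TestPir:
    def test_alignment_rows_consistent(self, divergent_pair):
        arch, scaffold, insert = divergent_pair
        pairing = pair_structures(scaffold, insert)
        loop = simple_loops(arch.labels)[0]
        d = enumerate_designs(loop, loop, pairing, scaffold, insert).designs[0]
        text = write_pir(d, scaffold, insert)

        from Bio import SeqIO
        entries = list(SeqIO.parse(io.StringIO(text), "pir"))
        assert len(entries) == 3
        rows = [str(e.seq) for e in entries]
        assert len({len(r) for r in rows}) == 1
        chimera_row = rows[-1]
        assert chimera_row.replace("-", "") == d.chimera_sequence
        scaffold_row = rows[0]
        kept_scaffold = "".join(
            c for c, p in zip(chimera_row, d.provenance) if p == "scaffold"
        )
        assert scaffold_row.replace("-", "") == kept_scaffold
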