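import random

import pytest

from transannot.orfs import Orf, find_orfs, top_orfs
from transannot.seqio import SequenceRecord, reverse_complement, translate

from conftest import random_nt
from oracles import six_frame_orfs


def _as_set(orfs):
    return {(o.strand, o.nt_start, o.nt_end, o.aa_seq) for o in orfs}


def _record(seq, rec_id="t"):
    return SequenceRecord(rec_id, seq, "", "nt")


class TestFindOrfs:
    def test_stop_free_sequence_gives_one_orf_per_frame(self):
        # 99 nt of codons that are stop-free in all six frames
        seq = "AAC" * 33
        orfs = find_orfs(_record(seq), min_aa=10)
        assert len(orfs) == 6
        assert sorted((o.strand, o.frame) for o in orfs) == [
            ("forward", 1), ("forward", 2), ("forward", 3),
            ("reverse", 1), ("reverse", 2), ("reverse", 3),
        ]

    def test_stop_to_stop_segmentation(self):
        orfs = [
            o for o in find_orfs(_record("ATGAAATAAATGCCCTAA"), min_aa=2)
            if o.strand == "forward" and o.frame == 1
        ]
        assert [(o.nt_start, o.nt_end, o.aa_seq) for o in orfs] == [
            (1, 6, "MK"),
            (10, 15, "MP"),
        ]

    def test_span_length_is_three_times_aa_length(self, rng):
        for _ in range(50):
            rec = _record(random_nt(rng, rng.randint(90, 600)))
            for o in find_orfs(rec, min_aa=5):
                assert o.nt_end - o.nt_start + 1 == 3 * len(o.aa_seq)
                assert "*" not in o.aa_seq

    def test_matches_brute_force_oracle(self, rng):
        """Six-frame translate-and-split oracle on seeded random sequences."""
        for _ in range(200):
            seq = random_nt(rng, rng.randint(200, 1500))
            got = _as_set(find_orfs(_record(seq), min_aa=10))
            assert got == set(six_frame_orfs(seq, 10))

    def test_strand_symmetry(self, rng):
        """ORFs of the reverse complement are the mirrored ORFs."""
        for _ in range(50):
            seq = random_nt(rng, rng.randint(200, 900))
            L = len(seq)
            fwd = _as_set(find_orfs(_record(seq), min_aa=8))
            rev = _as_set(find_orfs(_record(reverse_complement(seq)), min_aa=8))
            mirrored = {
                ("reverse" if strand == "forward" else "forward", L - e + 1, L - s + 1, aa)
                for strand, s, e, aa in rev
            }
            assert fwd == mirrored

    def test_residue_conservation_per_frame(self, rng):
        """Each frame's stretches (kept plus sub-threshold) reassemble that
        frame's full translation with stops removed."""
        seq = random_nt(rng, 600)
        orfs = find_orfs(_record(seq), min_aa=1)
        for off in range(3):
            full = translate(seq, off)
            frame_orfs = sorted(
                (o for o in orfs if o.strand == "forward" and o.frame == off + 1),
                key=lambda o: o.nt_start,
            )
            assert "".join(o.aa_seq for o in frame_orfs) == full.replace("*", "")

    def test_orf_index_unique_and_ordered(self, rng):
        orfs = find_orfs(_record(random_nt(rng, 800)), min_aa=5)
        assert [o.orf_index for o in orfs] == list(range(1, len(orfs) + 1))
        strands = [o.strand for o in orfs]
        assert strands == sorted(strands)  # forward block before reverse block

    def test_rejects_protein_record(self):
        with pytest.raises(ValueError):
            find_orfs(SequenceRecord("p", "MKLV", "", "aa"))


class TestTopOrfs:
    def _make(self, lengths, strand="forward"):
        return [
            Orf("t", i + 1, strand, 1, 10 * i + 1, 10 * i + 3 * n, "A" * n)
            for i, n in enumerate(lengths)
        ]

    def test_order_statistic(self):
        top = top_orfs(self._make([50, 40, 30, 20, 10, 5]), k=3)
        assert [len(o.aa_seq) for o in top] == [50, 40, 30]

    def test_forward_ranks_before_reverse_on_ties(self):
        fwd = Orf("t", 1, "forward", 1, 10, 39, "A" * 10)
        rev = Orf("t", 2, "reverse", 1, 1, 30, "A" * 10)
        assert top_orfs([rev, fwd], k=1) == [fwd]

    def test_full_k_is_permutation(self, rng):
        orfs = self._make([rng.randint(5, 60) for _ in range(12)])
        assert sorted(top_orfs(orfs, k=len(orfs)), key=id) == sorted(orfs, key=id)

    def test_fewer_than_k_returned(self):
        assert len(top_orfs(self._make([10, 20]), k=3)) == 2

    def test_mixed_transcripts_rejected(self):
        a = Orf("t1", 1, "forward", 1, 1, 30, "A" * 10)
        b = Orf("t2", 1, "forward", 1, 1, 30, "A" * 10)
        with pytest.raises(ValueError):
            top_orfs([a, b])


def test_orf_id_and_coordinate_display():
    fwd = Orf("C1089_G1_I1", 64, "forward", 1, 1117, 2631, "A" * 505)
    rev = Orf("C19241_G1_I1", 115, "reverse", 2, 4096, 4509, "A" * 138)
    assert fwd.orf_id == "C1089_G1_I1_ORF_64"
    assert fwd.coord_label == "fwd: 1117-2631"
    assert rev.coord_label == "reverse: 4509-4096"
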