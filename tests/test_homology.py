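import math
import random

import pytest

from transannot.homology import (
    GenomeHit,
    HitTableError,
    PairwiseScorer,
    ProteinHit,
    ScorerParams,
    best_hit_per_query,
    bitscore_from_raw,
    evalue_from_bitscore,
    map_transcripts_to_genome,
    parse_hit_table,
    write_hit_table,
)
from transannot.seqio import SequenceRecord

from conftest import random_aa, random_nt
from oracles import blosum62_linker_neutral, brute_best_hits, gotoh_local_score

BLOSUM62_DIAG = {"M": 5, "K": 5, "W": 11, "V": 4, "A": 4, "L": 4, "P": 7, "G": 6}


def _hit(q="q", s="s", e=1e-10, bits=100.0):
    return ProteinHit(q, s, 98.0, 100, 2, 0, 1, 100, 1, 100, e, bits)


class TestHitTable:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\tP30986\t98.0\t100\t1\t0\t1\t100\t1\t100\t2e-50\t180\n")
        (h,) = parse_hit_table(p, "protein")
        assert h.query_id == "q1" and h.subject_id == "P30986"
        assert h.evalue == 2e-50 and h.bitscore == 180

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert parse_hit_table(p) == []

    def test_zero_evalue_accepted(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\ts\t100.00\t500\t0\t0\t1\t500\t1\t500\t0.0\t1000\n")
        assert parse_hit_table(p)[0].evalue == 0.0

    def test_round_trip_500_random_lines(self, tmp_path, rng):
        hits = [
            ProteinHit(
                f"q{i}", f"s{rng.randint(0, 50)}", round(rng.uniform(30, 100), 2),
                rng.randint(20, 500), rng.randint(0, 40), rng.randint(0, 5),
                1, 100, 1, 100,
                float(f"{rng.uniform(1, 9.9):.2f}e-{rng.randint(3, 180)}"),
                round(rng.uniform(40, 900), 1),
            )
            for i in range(500)
        ]
        p = tmp_path / "rt.tsv"
        write_hit_table(hits, p)
        assert parse_hit_table(p, "protein") == hits

    @pytest.mark.parametrize(
        "line", ["q\ts\tonly\tfour\tcols", "q\ts\tNaN?\t1\t0\t0\t1\t2\t1\t2\tbad\t60"]
    )
    def test_malformed_line_reports_line_number(self, tmp_path, line):
        p = tmp_path / "bad.tsv"
        p.write_text("q\ts\t9.0\t10\t0\t0\t1\t10\t1\t10\t1e-5\t30\n" + line + "\n")
        with pytest.raises(HitTableError, match=":2:"):
            parse_hit_table(p)


class TestBestHit:
    def test_lowest_evalue_wins(self):
        hits = [_hit(e=1e-10), _hit(e=1e-80)]
        assert best_hit_per_query(hits)["q"].evalue == 1e-80

    def test_evalue_tie_broken_by_bitscore(self):
        hits = [_hit(e=1e-10, bits=60), _hit(e=1e-10, bits=75)]
        assert best_hit_per_query(hits)["q"].bitscore == 75

    def test_matches_brute_force_on_random_tables(self, rng):
        hits = [
            _hit(q=f"q{rng.randint(0, 20)}", e=10.0 ** -rng.randint(1, 99),
                 bits=rng.choice([50.0, 60.0, 75.0]))
            for _ in range(300)
        ]
        assert best_hit_per_query(hits) == brute_best_hits(hits)


class TestKarlinAltschul:
    # hand-computed from S' = (lambda*S - ln K)/ln 2 and E = m*n*2^-S'
    CASES = [
        # (lambda, K, m, n, S) -> (bitscore, evalue)
        (0.267, 0.041, 10**6, 100, 100, 43.1281899, 1.04021e-5),
        (0.318, 0.130, 1000, 30, 50, 25.8822676, 4.85045e-4),
        (0.267, 0.041, 5 * 10**5, 200, 500, 197.2080202, 4.30993e-52),
    ]

    @pytest.mark.parametrize("lam,K,m,n,S,bits,evalue", CASES)
    def test_formulas_against_hand_computation(self, lam, K, m, n, S, bits, evalue):
        params = ScorerParams(lam=lam, K=K, m=m, n=n)
        got_bits = bitscore_from_raw(S, params)
        assert got_bits == pytest.approx(bits, rel=1e-6)
        assert evalue_from_bitscore(got_bits, params) == pytest.approx(evalue, rel=1e-5)

    def test_bitscore_increasing_evalue_decreasing(self):
        params = ScorerParams(m=10**6, n=100)
        bits = [bitscore_from_raw(s, params) for s in range(10, 200, 10)]
        assert bits == sorted(bits)
        evals = [evalue_from_bitscore(b, params) for b in bits]
        assert evals == sorted(evals, reverse=True)


@pytest.fixture(scope="module")
def scorer():
    return PairwiseScorer(ScorerParams(m=10**6))


class TestPairwiseScorer:
    def test_self_alignment_scores_diagonal_sum(self, scorer):
        seq = "MKWVALPG"
        expected = sum(BLOSUM62_DIAG[c] for c in seq)
        assert scorer.raw_score(seq, seq) == expected

    def test_evalue_decreases_with_longer_identity(self, scorer):
        short = scorer.align("q", "MKWV" * 5, "s", "MKWV" * 5)
        long = scorer.align("q", "MKWV" * 25, "s", "MKWV" * 25)
        assert long.evalue < short.evalue

    def test_no_positive_pair_scores_zero(self, scorer):
        # linker-only query scores 0 against everything -> no hit
        assert scorer.raw_score("ZZZZ", "MKWV") == 0
        assert scorer.align("q", "ZZZZ", "s", "MKWV") is None

    def test_matches_exhaustive_dp_oracle(self, rng):
        """Raw-score equality with an independent Gotoh DP on 200 random
        pairs of length <= 25 (including linker residues)."""
        scorer = PairwiseScorer(ScorerParams(m=1000))
        sub = blosum62_linker_neutral()
        for _ in range(200):
            a = random_aa(rng, rng.randint(1, 25))
            b = random_aa(rng, rng.randint(1, 25))
            if rng.random() < 0.3:
                i = rng.randint(0, len(a) - 1)
                a = a[:i] + "Z" * rng.randint(1, 3) + a[i:]
            assert scorer.raw_score(a, b) == gotoh_local_score(a, b, sub)

    def test_score_symmetric_under_swap(self, rng):
        scorer = PairwiseScorer(ScorerParams(m=1000))
        for _ in range(50):
            a, b = random_aa(rng, 30), random_aa(rng, 30)
            assert scorer.raw_score(a, b) == scorer.raw_score(b, a)

    def test_appending_residues_never_decreases_score(self, rng):
        scorer = PairwiseScorer(ScorerParams(m=1000))
        for _ in range(30):
            a, b = random_aa(rng, 20), random_aa(rng, 20)
            base = scorer.raw_score(a, b)
            assert scorer.raw_score(a + random_aa(rng, 10), b) >= base

    def test_linker_neutral_in_context(self, scorer):
        """Inserting Z into a perfect match neither rewards nor costs more
        than the gap it stands for."""
        plain = scorer.raw_score("MKWVALPG", "MKWVALPG")
        with_z = scorer.raw_score("MKWVZZZALPG", "MKWVALPG")
        assert with_z <= plain
        assert with_z >= plain - (11 + 3)  # at worst a 3-residue gap

    def test_search_finds_diverged_homolog_only(self, rng):
        scorer = PairwiseScorer(ScorerParams(m=10000))
        target = random_aa(rng, 120)
        homolog = "".join(
            c if rng.random() > 0.1 else random_aa(rng, 1) for c in target
        )
        decoys = {f"d{i}": random_aa(rng, 120) for i in range(20)}
        hits = scorer.search({"q": target}, {"h": homolog, **decoys})
        assert [h.subject_id for h in hits] == ["h"]
        assert hits[0].evalue < 1e-20


class TestGenomeMapper:
    def test_embedded_transcript_maps_with_high_bitscore(self, rng):
        scaffold = random_nt(rng, 3000)
        insert = scaffold[1000:1900]
        genome = [SequenceRecord("scafA", scaffold, "", "nt")]
        tr = [SequenceRecord("t1", insert, "", "nt")]
        (hit,) = map_transcripts_to_genome(tr, genome)
        assert hit.scaffold_id == "scafA"
        assert hit.bitscore > 75
        assert (hit.s_start, hit.s_end) == (1001, 1900)

    def test_reverse_orientation_found(self, rng):
        from transannot.seqio import reverse_complement

        scaffold = random_nt(rng, 2000)
        genome = [SequenceRecord("scafA", scaffold, "", "nt")]
        tr = [SequenceRecord("t1", reverse_complement(scaffold[500:1200]), "", "nt")]
        (hit,) = map_transcripts_to_genome(tr, genome)
        assert hit.scaffold_id == "scafA" and hit.align_len == 700

    def test_foreign_sequence_yields_no_hit(self, rng):
        genome = [SequenceRecord("scafA", random_nt(rng, 3000), "", "nt")]
        tr = [SequenceRecord("alien", random_nt(rng, 800), "", "nt")]
        assert map_transcripts_to_genome(tr, genome) == []
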