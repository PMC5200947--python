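import math

import pytest

from transannot.orfs import find_orfs
from transannot.seqio import SequenceRecord, reverse_complement, translate
from transannot.simulate import (
    FUSION_SPACER,
    SimConfig,
    expected_outcomes,
    read_truth,
    simulate,
    write_simulation,
)


@pytest.fixture(scope="module")
def default_sim():
    return simulate(SimConfig(n_genes=80, seed=11))


class TestSimulate:
    def test_degenerate_config_all_clean(self):
        cfg = SimConfig(n_genes=25, p_break=1e-12, p_fusion=1e-12,
                        p_contaminant=1e-12, p_redundant=1e-12, seed=3)
        sim = simulate(cfg)
        assert len(sim.transcriptome) == 25
        assert all(r.label == "clean" for r in sim.truth)

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(n_genes=30, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_simulation(simulate(cfg), d1)
        write_simulation(simulate(cfg), d2)
        for name in ("genome.fasta", "database.fasta", "transcriptome.fasta", "truth.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_label_counts_within_binomial_3_sigma(self):
        cfg = SimConfig(n_genes=1000, seed=42)
        sim = simulate(cfg)
        counts = {}
        for row in sim.truth:
            counts[row.label] = counts.get(row.label, 0) + 1
        n = cfg.n_genes
        # broken artifacts (both flavours; pairs contribute two rows)
        n_broken = counts.get("broken_single", 0) + counts.get("broken_pair", 0) // 2
        for observed, p in [
            (n_broken, cfg.p_break),
            (counts.get("fusion", 0), cfg.p_fusion),
            (counts.get("contaminant", 0), cfg.p_contaminant),
            (counts.get("redundant", 0), cfg.p_redundant),
        ]:
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * sigma

    def test_truth_and_transcriptome_in_bijection(self, default_sim):
        truth_ids = [r.transcript_id for r in default_sim.truth]
        fasta_ids = [t.id for t in default_sim.transcriptome]
        assert sorted(truth_ids) == sorted(fasta_ids)
        assert len(set(truth_ids)) == len(truth_ids)

    def test_fusion_spacer_stops_in_all_six_frames(self):
        for s in (FUSION_SPACER, reverse_complement(FUSION_SPACER)):
            for off in range(3):
                assert "*" in translate(s, off)

    def test_fusion_transcripts_carry_both_proteins_in_separate_orfs(self, default_sim):
        tr = {t.id: t for t in default_sim.transcriptome}
        fusions = [r for r in default_sim.truth if r.label == "fusion"]
        assert fusions, "config should plant at least one fusion at this size"
        for row in fusions:
            p1, p2 = row.true_protein.split("|")
            orf_aas = [o.aa_seq for o in find_orfs(tr[row.transcript_id], 30)]
            host1 = next(a for a in orf_aas if p1 in a)
            host2 = next(a for a in orf_aas if p2 in a)
            assert host1 != host2

    def test_clean_transcript_contains_cds(self, default_sim):
        tr = {t.id: t for t in default_sim.transcriptome}
        for row in default_sim.truth:
            if row.label == "clean":
                aas = [o.aa_seq for o in find_orfs(tr[row.transcript_id], 30)]
                assert any(row.true_protein in a for a in aas)

    def test_database_homolog_identity_close_to_divergence(self, default_sim):
        truth_by_gene = {}
        for row in default_sim.truth:
            if row.label == "clean":
                truth_by_gene[row.gene_ids[0]] = row.true_protein
        db = {d.id: d.residues for d in default_sim.database}
        for gid, protein in truth_by_gene.items():
            homolog = db[f"SP{gid}"]
            assert len(homolog) == len(protein)
            ident = sum(a == b for a, b in zip(protein, homolog)) / len(protein)
            # 3 sigma below the expected 90% identity
            sigma = math.sqrt(0.1 * 0.9 / len(protein))
            assert ident >= 0.9 - 3 * sigma

    def test_redundant_is_exact_substring_of_parent(self, default_sim):
        tr = {t.id: t for t in default_sim.transcriptome}
        for row in default_sim.truth:
            if row.label == "redundant":
                assert tr[row.transcript_id].residues in tr[row.partner_id].residues

    def test_contaminant_absent_from_genome(self, default_sim):
        genome_seq = "".join(g.residues for g in default_sim.genome)
        for row in default_sim.truth:
            if row.label == "contaminant":
                probe = {row.transcript_id}
                tr = next(t for t in default_sim.transcriptome if t.id in probe)
                assert tr.residues[:50] not in genome_seq

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_break=0.7, p_fusion=0.5)
        with pytest.raises(ValueError):
            SimConfig(p_contaminant=1.5)


class TestTruthIO:
    def test_truth_round_trip(self, default_sim, tmp_path):
        paths = write_simulation(default_sim, tmp_path)
        back = read_truth(paths["truth"])
        assert back == default_sim.truth


class TestExpectedOutcomes:
    def test_contaminant_expected_excluded(self, default_sim):
        expected = expected_outcomes(default_sim.truth)
        for row in default_sim.truth:
            exp = expected[row.transcript_id]
            if row.label == "contaminant":
                assert exp == {"stage": "excluded", "category": None, "n_records": 0}
            elif row.label == "fusion":
                assert exp["n_records"] == len(row.gene_ids) == 2

    def test_total_expected_records_match_gene_count(self):
        cfg = SimConfig(n_genes=50, p_contaminant=1e-12, p_redundant=1e-12, seed=9)
        sim = simulate(cfg)
        expected = expected_outcomes(sim.truth)
        total = sum(e["n_records"] for e in expected.values())
        assert total == 50  # one record per gene after repair and split
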