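"""Seeded synthetic data: genome, protein database, transcriptome, truth.

The generator emulates, at toy scale, the inputs the annotation flow
consumes in practice — a de novo assembled transcriptome, a draft genome,
and a protein database of diverged homologs — together with the assembler
artifacts the pipeline exists to repair:

* ``clean``          — one gene, one intact transcript (CDS plus random UTRs).
* ``broken_single``  — the CDS emitted with an internal deletion that
  shifts the frame, so the transcript carries two ORFs matching the same
  protein (repaired by a 'ZZZ' linker merge). Default rate for breaks
  overall is 5%, matching the fraction of transcripts observed with two
  or more same-protein ORFs in real de novo assemblies.
* ``broken_pair``    — the CDS emitted as two transcripts that retain a
  short exact overlap (repaired by a cross-transcript overlap merge).
  Breaks are split 50/50 between the two flavours.
* ``fusion``         — two genes on one chimeric transcript, separated by
  a spacer with stop codons in all six frames (~3% of transcripts, the
  observed rate of multi-gene chimeras).
* ``contaminant``    — a transcript with no genome locus at all (10%),
  standing in for reads from other organisms.
* ``redundant``      — an exact substring of a clean transcript (5%),
  absorbed by deduplication.

Every transcript gets exactly one truth row, so expected pipeline
behaviour is computable record by record.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .orfs import find_orfs, top_orfs
from .seqio import CODON_TABLE, SequenceRecord, write_fasta

__all__ = [
    "SimConfig",
    "TruthRow",
    "SimResult",
    "simulate",
    "write_simulation",
    "read_truth",
    "expected_outcomes",
    "evaluate_run",
    "FUSION_SPACER",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")
_CODONS_FOR = {aa: [c for c, a in CODON_TABLE.items() if a == aa] for aa in _AA20}

# Stop codons in all six reading frames; CTAG is its own reverse complement,
# so the reverse strand repeats the same frames.
FUSION_SPACER = "CTAG" * 9


@dataclass
class SimConfig:
    """Study conditions for the synthetic transcriptome.

    Artifact rates default to the observed rates in real de novo
    assemblies (5% broken, ~3% chimeric); divergence is the per-residue
    substitution probability between a true protein and its database
    homolog (10%, a typical cross-species distance within a plant family).
    """

    n_genes: int = 200
    n_scaffolds: int = 12
    intergenic_range: Tuple[int, int] = (200, 600)
    protein_len_range: Tuple[int, int] = (100, 300)
    divergence: float = 0.10
    p_break: float = 0.05
    p_fusion: float = 0.03
    p_contaminant: float = 0.10
    p_redundant: float = 0.05
    deletion_range: Tuple[int, int] = (30, 90)
    utr_range: Tuple[int, int] = (0, 300)
    overlap_aa_range: Tuple[int, int] = (8, 15)
    min_piece_aa: int = 40
    seed: int = 42

    def __post_init__(self):
        for p in (self.p_break, self.p_fusion, self.p_contaminant, self.p_redundant):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_break + self.p_fusion > 1:
            raise ValueError("p_break + p_fusion must be <= 1")
        if self.protein_len_range[0] < 2 * self.min_piece_aa + 5:
            raise ValueError(
                "protein_len_range minimum too small for min_piece_aa break pieces"
            )


@dataclass
class TruthRow:
    transcript_id: str
    label: str  # clean | broken_single | broken_pair | fusion | contaminant | redundant
    gene_ids: Tuple[str, ...]
    scaffold: str
    start: int  # 1-based CDS coordinates on the scaffold; 0 for contaminants
    end: int
    partner_id: str  # other member of a broken pair, or parent of a redundant
    true_protein: str  # for fusions: proteins joined with '|'


@dataclass
class SimResult:
    genome: List[SequenceRecord]
    database: List[SequenceRecord]
    transcriptome: List[SequenceRecord]
    truth: List[TruthRow]


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_AA20) for _ in range(n))


def _cds_for(rng: random.Random, protein: str) -> str:
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


def _mutate(rng: random.Random, protein: str, rate: float) -> str:
    out = []
    for aa in protein:
        if rng.random() < rate:
            out.append(rng.choice([a for a in _AA20 if a != aa]))
        else:
            out.append(aa)
    return "".join(out)


def _top_orf_seqs(seq: str, k: int = 3, min_aa: int = 30) -> List[str]:
    rec = SequenceRecord("probe", seq, "", "nt")
    return [o.aa_seq for o in top_orfs(find_orfs(rec, min_aa), k)]


def _contains_distinct(top_aas: List[str], probes: List[str]) -> bool:
    """Each probe substring found in a *different* member of top_aas."""
    used: set = set()
    for probe in probes:
        hit = next(
            (i for i, aa in enumerate(top_aas) if i not in used and probe in aa), None
        )
        if hit is None:
            return False
        used.add(hit)
    return True


def simulate(config: SimConfig) -> SimResult:
    """Generate genome, database, transcriptome and truth for one seed.

    Deterministic: a fixed seed yields byte-identical outputs. Planted
    artifacts are validated to exhibit their defining ORF structure —
    e.g. a broken transcript really does carry both fragment ORFs among
    its three longest — redrawing the random split point and UTR padding
    when a draw happens to bury a fragment under a chance ORF from
    untranslated or antisense sequence. Without this the truth label
    would describe an artifact the transcript does not actually contain.
    """
    rng = random.Random(config.seed)
    max_redraws = 25

    # genes: true protein, CDS, database homolog
    genes = []
    for g in range(config.n_genes):
        protein = _random_protein(rng, rng.randint(*config.protein_len_range))
        genes.append(
            {
                "id": f"G{g:04d}",
                "protein": protein,
                "cds": _cds_for(rng, protein),
                "homolog": _mutate(rng, protein, config.divergence),
            }
        )

    # placement: genes assigned to scaffolds round-robin, separated by
    # random intergenic spacers; forward strand (transcripts are sense mRNA)
    scaffold_parts: List[List[str]] = [[] for _ in range(config.n_scaffolds)]
    scaffold_pos = [0] * config.n_scaffolds
    for i, gene in enumerate(genes):
        si = i % config.n_scaffolds
        spacer = _random_nt(rng, rng.randint(*config.intergenic_range))
        scaffold_parts[si].append(spacer)
        scaffold_pos[si] += len(spacer)
        locus = gene["cds"] + rng.choice(_STOPS)
        gene["scaffold"] = f"SCAF{si:03d}"
        gene["start"] = scaffold_pos[si] + 1
        gene["end"] = scaffold_pos[si] + len(locus)
        scaffold_parts[si].append(locus)
        scaffold_pos[si] += len(locus)
    for si in range(config.n_scaffolds):
        tail = _random_nt(rng, rng.randint(*config.intergenic_range))
        scaffold_parts[si].append(tail)
    genome = [
        SequenceRecord(f"SCAF{si:03d}", "".join(parts), "synthetic scaffold", "nt")
        for si, parts in enumerate(scaffold_parts)
    ]

    database = [
        SequenceRecord(f"SP{g['id']}", g["homolog"], f"homolog of {g['id']}", "aa")
        for g in genes
    ]

    # per-gene category draw; fusions consume the next unconsumed gene
    transcripts: List[SequenceRecord] = []
    truth: List[TruthRow] = []
    t_counter = 0

    def next_tid() -> str:
        nonlocal t_counter
        t_counter += 1
        return f"T{t_counter:05d}"

    def utr(_rng) -> str:
        return _random_nt(_rng, _rng.randint(*config.utr_range))

    consumed = [False] * config.n_genes
    clean_indices: List[int] = []
    for i, gene in enumerate(genes):
        if consumed[i]:
            continue
        consumed[i] = True
        r = rng.random()
        partner_idx = next((j for j in range(i + 1, config.n_genes) if not consumed[j]), None)
        if r < config.p_fusion and partner_idx is not None:
            consumed[partner_idx] = True
            other = genes[partner_idx]
            tid = next_tid()
            for attempt in range(max_redraws):
                # Chance ORFs in the alternate frames of one constituent CDS
                # can outrank the other gene's true ORF; redrawing UTRs alone
                # cannot fix that, so later attempts synonymously re-encode
                # one CDS copy on the chimera (the other stays genome-exact,
                # keeping the genome filter satisfied).
                cds1, cds2 = gene["cds"], other["cds"]
                if attempt > 0 and attempt % 2 == 1:
                    cds1 = _cds_for(rng, gene["protein"])
                elif attempt > 0:
                    cds2 = _cds_for(rng, other["protein"])
                seq = (
                    utr(rng)
                    + cds1
                    + rng.choice(_STOPS)
                    + FUSION_SPACER
                    + cds2
                    + rng.choice(_STOPS)
                    + utr(rng)
                )
                if _contains_distinct(
                    _top_orf_seqs(seq), [gene["protein"], other["protein"]]
                ):
                    break
            transcripts.append(SequenceRecord(tid, seq, "fusion", "nt"))
            truth.append(
                TruthRow(
                    tid, "fusion", (gene["id"], other["id"]), gene["scaffold"],
                    gene["start"], gene["end"], "",
                    gene["protein"] + "|" + other["protein"],
                )
            )
        elif r < config.p_fusion + config.p_break:
            protein, cds = gene["protein"], gene["cds"]
            n_aa = len(protein)
            if rng.random() < 0.5:
                # same-transcript break: internal deletion with frameshift
                tid = next_tid()
                for _ in range(max_redraws):
                    k = rng.randint(config.min_piece_aa, n_aa - config.min_piece_aa)
                    del_len = rng.randint(*config.deletion_range)
                    if del_len % 3 == 0:
                        del_len += 1
                    seq = (
                        utr(rng)
                        + cds[: 3 * k]
                        + cds[3 * k + del_len :]
                        + rng.choice(_STOPS)
                        + utr(rng)
                    )
                    # both fragments must surface among the 3 longest ORFs
                    probes = [protein[:k], protein[k + del_len // 3 + 1 :]]
                    if _contains_distinct(_top_orf_seqs(seq), probes):
                        break
                transcripts.append(SequenceRecord(tid, seq, "broken(deletion)", "nt"))
                truth.append(
                    TruthRow(
                        tid, "broken_single", (gene["id"],), gene["scaffold"],
                        gene["start"], gene["end"], "", protein,
                    )
                )
            else:
                # two-transcript break with a retained exact overlap
                tid1, tid2 = next_tid(), next_tid()
                for _ in range(max_redraws):
                    k = rng.randint(config.min_piece_aa, n_aa - config.min_piece_aa)
                    ov = min(rng.randint(*config.overlap_aa_range), n_aa - k - 1)
                    seq1 = utr(rng) + cds[: 3 * (k + ov)]
                    seq2 = cds[3 * k :] + rng.choice(_STOPS) + utr(rng)
                    if _contains_distinct(_top_orf_seqs(seq1), [protein[: k + ov]]) and \
                       _contains_distinct(_top_orf_seqs(seq2), [protein[k:]]):
                        break
                transcripts.append(SequenceRecord(tid1, seq1, "broken(pair 1)", "nt"))
                transcripts.append(SequenceRecord(tid2, seq2, "broken(pair 2)", "nt"))
                truth.append(
                    TruthRow(
                        tid1, "broken_pair", (gene["id"],), gene["scaffold"],
                        gene["start"], gene["end"], tid2, protein,
                    )
                )
                truth.append(
                    TruthRow(
                        tid2, "broken_pair", (gene["id"],), gene["scaffold"],
                        gene["start"], gene["end"], tid1, protein,
                    )
                )
        else:
            tid = next_tid()
            seq = utr(rng) + gene["cds"] + rng.choice(_STOPS) + utr(rng)
            transcripts.append(SequenceRecord(tid, seq, "clean", "nt"))
            truth.append(
                TruthRow(
                    tid, "clean", (gene["id"],), gene["scaffold"],
                    gene["start"], gene["end"], "", gene["protein"],
                )
            )
            clean_indices.append(len(transcripts) - 1)

    # contaminants: composition-random sequences with no genome locus
    n_contam = sum(1 for _ in range(config.n_genes) if rng.random() < config.p_contaminant)
    for _ in range(n_contam):
        tid = next_tid()
        seq = _random_nt(rng, rng.randint(400, 2000))
        transcripts.append(SequenceRecord(tid, seq, "contaminant", "nt"))
        truth.append(TruthRow(tid, "contaminant", (), "-", 0, 0, "", ""))

    # redundant transcripts: exact substrings of clean ones (UTR-trimmed)
    n_redundant = sum(1 for _ in range(config.n_genes) if rng.random() < config.p_redundant)
    truth_by_tid = {row.transcript_id: row for row in truth}
    for _ in range(n_redundant):
        if not clean_indices:
            break
        parent = transcripts[rng.choice(clean_indices)]
        prow = truth_by_tid[parent.id]
        d5 = rng.randint(0, 40)
        d3 = rng.randint(0, 40)
        sub = parent.residues[d5 : len(parent.residues) - d3]
        tid = next_tid()
        transcripts.append(SequenceRecord(tid, sub, f"substring of {parent.id}", "nt"))
        truth.append(
            TruthRow(
                tid, "redundant", prow.gene_ids, prow.scaffold,
                prow.start, prow.end, parent.id, prow.true_protein,
            )
        )

    return SimResult(genome, database, transcripts, truth)


_TRUTH_COLUMNS = [
    "transcript_id", "label", "gene_ids", "scaffold", "start", "end",
    "partner_id", "true_protein",
]


def write_simulation(result: SimResult, outdir: str | Path) -> Dict[str, Path]:
    """Write the four study files into ``outdir`` and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "database": outdir / "database.fasta",
        "transcriptome": outdir / "transcriptome.fasta",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(result.genome, paths["genome"])
    write_fasta(result.database, paths["database"])
    write_fasta(result.transcriptome, paths["transcriptome"])
    with open(paths["truth"], "w") as out:
        out.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for row in result.truth:
            out.write(
                "\t".join(
                    [
                        row.transcript_id,
                        row.label,
                        ",".join(row.gene_ids),
                        row.scaffold,
                        str(row.start),
                        str(row.end),
                        row.partner_id,
                        row.true_protein,
                    ]
                )
                + "\n"
            )
    return paths


def read_truth(path: str | Path) -> List[TruthRow]:
    rows = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth table columns {header}")
        for line in handle:
            cols = line.rstrip("\n").split("\t")
            rows.append(
                TruthRow(
                    cols[0], cols[1],
                    tuple(cols[2].split(",")) if cols[2] else (),
                    cols[3], int(cols[4]), int(cols[5]), cols[6], cols[7],
                )
            )
    return rows


def expected_outcomes(truth: List[TruthRow]) -> Dict[str, Dict[str, object]]:
    """Expected pipeline behaviour per transcript, from the truth table.

    Returns transcript_id -> {stage, category, n_records} where
    ``n_records`` is the number of annotation records the transcript
    should contribute after repair and dedup (pair members share one
    merged record, counted on the first member).
    """
    out: Dict[str, Dict[str, object]] = {}
    for row in truth:
        if row.label == "clean":
            out[row.transcript_id] = {"stage": "annotated", "category": "UNIQUE", "n_records": 1}
        elif row.label == "broken_single":
            out[row.transcript_id] = {"stage": "annotated", "category": "MULTI_SAME", "n_records": 1}
        elif row.label == "broken_pair":
            first = row.transcript_id < row.partner_id
            out[row.transcript_id] = {
                "stage": "annotated",
                "category": "UNIQUE",
                "n_records": 1 if first else 0,
            }
        elif row.label == "fusion":
            out[row.transcript_id] = {
                "stage": "annotated",
                "category": "MULTI_DIFF",
                "n_records": len(row.gene_ids),
            }
        elif row.label == "contaminant":
            out[row.transcript_id] = {"stage": "excluded", "category": None, "n_records": 0}
        elif row.label == "redundant":
            out[row.transcript_id] = {"stage": "dedup_absorbed", "category": "UNIQUE", "n_records": 0}
        else:
            raise ValueError(f"unknown truth label {row.label!r}")
    return out


def evaluate_run(result, truth: List[TruthRow]) -> Dict[str, float]:
    """Score a pipeline run against the ground truth.

    Returns fractions in [0, 1]:

    * ``contaminant_excluded`` — planted contaminants in the excluded list;
    * ``fusion_multi_diff`` — fusions classified MULTI_DIFF;
    * ``fusion_split_correct`` — fusions yielding exactly one split record
      per constituent gene (pre-dedup provenance);
    * ``broken_repaired`` — break artifacts repaired: an accepted linker
      merge for single-transcript breaks, an accepted cross-transcript
      merge joining both members for two-transcript breaks;
    * ``clean_recovered`` — clean genes ending as exactly one surviving
      record (counting absorbed redundant copies as that record) whose
      sequence contains the true protein, allowing terminal truncation;
    * ``gate_violations`` — accepted merges violating the E-value gate
      (count, not a fraction; must be 0).
    """
    from .pipeline import MULTI_DIFF, MULTI_SAME, merge_gate

    by_label: Dict[str, List[TruthRow]] = {}
    for row in truth:
        by_label.setdefault(row.label, []).append(row)

    excluded = set(result.excluded)
    contam = by_label.get("contaminant", [])
    contaminant_excluded = (
        sum(1 for r in contam if r.transcript_id in excluded) / len(contam)
        if contam else 1.0
    )

    fusions = by_label.get("fusion", [])
    n_md = sum(
        1
        for r in fusions
        if r.transcript_id in result.classifications
        and result.classifications[r.transcript_id].category == MULTI_DIFF
    )
    fusion_multi_diff = n_md / len(fusions) if fusions else 1.0

    # split correctness: count records (surviving or absorbed) per fusion
    absorbed_ids = {aid for rec in result.records for aid in rec.absorbed}
    produced_ids = {rec.output_id for rec in result.records} | absorbed_ids
    n_split_ok = 0
    for r in fusions:
        n_parts = sum(
            1
            for i in range(len(r.gene_ids))
            if f"{r.transcript_id}_{chr(ord('A') + i)}" in produced_ids
        )
        if n_parts == len(r.gene_ids):
            n_split_ok += 1
    fusion_split_correct = n_split_ok / len(fusions) if fusions else 1.0

    # broken repairs
    accepted_same = {
        d.input_ids[0].rsplit("_ORF_", 1)[0]
        for d in result.merge_log
        if d.accepted and d.kind == "same_transcript"
    }
    singles = by_label.get("broken_single", [])
    n_single_ok = sum(1 for r in singles if r.transcript_id in accepted_same)
    pairs = by_label.get("broken_pair", [])
    pair_keys = {tuple(sorted((r.transcript_id, r.partner_id))) for r in pairs}
    merged_pairs = set()
    for rec in result.records:
        if rec.provenance == "cross_merged" and len(rec.transcript_ids) >= 2:
            for a in rec.transcript_ids:
                for b in rec.transcript_ids:
                    if a < b:
                        merged_pairs.add((a, b))
    n_pair_ok = sum(1 for key in pair_keys if key in merged_pairs)
    n_broken = len(singles) + len(pair_keys)
    broken_repaired = (
        (n_single_ok + n_pair_ok) / n_broken if n_broken else 1.0
    )

    # clean recovery: exactly one surviving record traces to the gene's
    # transcripts (redundant copies may be absorbed into it) and carries
    # the true protein
    redundant_parents: Dict[str, List[str]] = {}
    for r in by_label.get("redundant", []):
        redundant_parents.setdefault(r.partner_id, []).append(r.transcript_id)
    cleans = by_label.get("clean", [])
    n_clean_ok = 0
    for r in cleans:
        family = {r.transcript_id} | set(redundant_parents.get(r.transcript_id, []))
        hosting = [
            rec
            for rec in result.records
            if family & set(rec.transcript_ids)
            or family & {a.split("_")[0] for a in rec.absorbed}
        ]
        if len(hosting) == 1:
            aa = hosting[0].aa_seq
            if r.true_protein in aa or aa in r.true_protein:
                n_clean_ok += 1
    clean_recovered = n_clean_ok / len(cleans) if cleans else 1.0

    gate_violations = sum(
        1
        for d in result.merge_log
        if d.accepted and not merge_gate(d.e1, d.e2, d.e_merged, 1.0)
    )

    return {
        "contaminant_excluded": contaminant_excluded,
        "fusion_multi_diff": fusion_multi_diff,
        "fusion_split_correct": fusion_split_correct,
        "broken_repaired": broken_repaired,
        "clean_recovered": clean_recovered,
        "gate_violations": float(gate_violations),
    }
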