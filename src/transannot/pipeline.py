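"""The annotation decision engine.

Stages, in order, mirroring the evidence-driven flow:

1. genome filter — transcripts with no genome alignment at or above the
   bitscore cutoff (default 75) are excluded as extraneous (contamination
   from other organisms); survivors are assigned their best scaffold.
2. ORF extraction — the three longest ORFs per surviving transcript.
3. classification — each transcript is binned by the pattern of its ORFs'
   significant protein-database hits (E <= 1e-8 and bitscore >= 60, both
   configurable): NO_MATCH, UNIQUE, MULTI_SAME (several ORFs, one gene:
   a broken transcript), MULTI_DIFF (several ORFs, several genes: a
   chimeric/fusion transcript).
4. repair — MULTI_SAME ORFs are merged with a ``ZZZ`` linker when the
   merged alignment's E-value improves on the best input E-value by the
   configured factor; MULTI_DIFF transcripts are split, one record per
   gene; records from different transcripts on one scaffold sharing a
   best subject are merged on an exact suffix–prefix amino-acid overlap,
   gated by the same E-value test.
5. dedup — records whose sequence is an exact substring of another are
   absorbed.

NO_MATCH transcripts are candidate novel genes or non-coding RNAs and are
reported separately, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .homology import (
    GenomeHit,
    PairwiseScorer,
    ProteinHit,
    ScorerParams,
    best_hit_per_query,
)
from .orfs import Orf, find_orfs, top_orfs
from .seqio import SequenceRecord

__all__ = [
    "Thresholds",
    "TranscriptClassification",
    "MergeDecision",
    "AnnotationRecord",
    "PipelineResult",
    "NO_MATCH",
    "UNIQUE",
    "MULTI_SAME",
    "MULTI_DIFF",
    "merge_gate",
    "genome_filter",
    "classify_transcript",
    "merge_same_transcript",
    "merge_cross_transcript",
    "longest_overlap",
    "split_transcript",
    "dedup_substrings",
    "run_pipeline",
]

NO_MATCH = "NO_MATCH"
UNIQUE = "UNIQUE"
MULTI_SAME = "MULTI_SAME"
MULTI_DIFF = "MULTI_DIFF"

LINKER = "ZZZ"


@dataclass
class Thresholds:
    """Every tunable cutoff of the pipeline, with its default.

    genome_bitscore_min: genome-filter cutoff in bits (inclusive).
    protein_evalue_max / protein_bitscore_min: a protein hit is
        *significant* only when both are satisfied.
    merge_improvement_factor: a merge is accepted when the merged E-value
        is at most min(e1, e2) times this factor ("significantly lower").
    min_overlap_aa: minimum exact suffix–prefix overlap for a
        cross-transcript merge.
    orf_min_aa: minimum ORF length in residues.
    comparison_evalue_max: cutoff for annotation-set comparison.
    """

    genome_bitscore_min: float = 75.0
    protein_evalue_max: float = 1e-8
    protein_bitscore_min: float = 60.0
    merge_improvement_factor: float = 1e-3
    min_overlap_aa: int = 7
    orf_min_aa: int = 30
    top_k_orfs: int = 3
    comparison_evalue_max: float = 1e-10

    def __post_init__(self):
        for name, val in self.__dict__.items():
            if val <= 0:
                raise ValueError(f"threshold {name} must be positive, got {val}")
        if self.merge_improvement_factor > 1:
            raise ValueError("merge_improvement_factor must be <= 1")


@dataclass
class TranscriptClassification:
    transcript_id: str
    category: str
    # ORF id -> best significant hit for that ORF
    orf_best: Dict[str, ProteinHit] = field(default_factory=dict)

    @property
    def subjects(self) -> List[str]:
        return sorted({h.subject_id for h in self.orf_best.values()})


@dataclass
class MergeDecision:
    kind: str  # "same_transcript" | "cross_transcript"
    input_ids: Tuple[str, str]
    subject_id: str
    e1: float
    e2: float
    e_merged: float
    accepted: bool
    merged_aa: str = ""
    overlap_aa: str = ""
    scaffold_id: str = ""


@dataclass
class AnnotationRecord:
    """A final output protein with provenance."""

    output_id: str
    aa_seq: str
    provenance: str  # representative | merged_linker | cross_merged | split_part
    transcript_ids: Tuple[str, ...]
    orf_ids: Tuple[str, ...]
    subject_id: str = ""
    evalue: float = float("inf")
    absorbed: List[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    records: List[AnnotationRecord]
    classifications: Dict[str, TranscriptClassification]
    merge_log: List[MergeDecision]
    excluded: List[str]
    unknown: List[str]
    scaffold_map: Dict[str, str]
    counts: Dict[str, int]


def merge_gate(e1: float, e2: float, e_merged: float, factor: float) -> bool:
    """Accept a merge iff the merged E-value improves on the better input
    E-value by at least the multiplicative ``factor``."""
    return e_merged <= min(e1, e2) * factor


def genome_filter(
    transcript_ids: Sequence[str],
    genome_hits: Iterable[GenomeHit],
    thresholds: Thresholds,
) -> Tuple[List[str], List[str], Dict[str, str]]:
    """Partition transcripts into (clean, excluded) by genome alignment.

    A transcript is clean iff it has at least one genome hit with
    bitscore >= the cutoff (inclusive); each clean transcript is assigned
    the scaffold of its best-scoring hit.
    """
    best: Dict[str, GenomeHit] = {}
    for h in genome_hits:
        cur = best.get(h.transcript_id)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.transcript_id] = h
    clean, excluded, scaffold_map = [], [], {}
    for tid in transcript_ids:
        h = best.get(tid)
        if h is not None and h.bitscore >= thresholds.genome_bitscore_min:
            clean.append(tid)
            scaffold_map[tid] = h.scaffold_id
        else:
            excluded.append(tid)
    return clean, excluded, scaffold_map


def classify_transcript(
    transcript_id: str,
    orf_hits: Iterable[ProteinHit],
    thresholds: Thresholds,
    known_orf_ids: Optional[Iterable[str]] = None,
) -> TranscriptClassification:
    """Bin a transcript by its ORFs' significant-hit pattern.

    Significant = E-value <= protein_evalue_max AND bitscore >=
    protein_bitscore_min (the two stated cutoffs applied conjunctively).
    With S the ORFs holding a significant hit and B(o) each ORF's best
    subject: |S|=0 -> NO_MATCH, |S|=1 -> UNIQUE, all B(o) equal ->
    MULTI_SAME, otherwise MULTI_DIFF.
    """
    known = set(known_orf_ids) if known_orf_ids is not None else None
    sig = [
        h
        for h in orf_hits
        if h.evalue <= thresholds.protein_evalue_max
        and h.bitscore >= thresholds.protein_bitscore_min
    ]
    if known is not None:
        bad = {h.query_id for h in sig} - known
        if bad:
            raise ValueError(f"hits reference unknown ORFs: {sorted(bad)}")
    orf_best = best_hit_per_query(sig)
    n = len(orf_best)
    if n == 0:
        category = NO_MATCH
    elif n == 1:
        category = UNIQUE
    elif len({h.subject_id for h in orf_best.values()}) == 1:
        category = MULTI_SAME
    else:
        category = MULTI_DIFF
    return TranscriptClassification(transcript_id, category, orf_best)


def merge_same_transcript(
    orf1: Orf,
    orf2: Orf,
    subject_id: str,
    subject_aa: str,
    e1: float,
    e2: float,
    scorer: PairwiseScorer,
    thresholds: Thresholds,
    subject_starts: Optional[Tuple[int, int]] = None,
) -> MergeDecision:
    """Attempt a linker merge of two ORFs of one broken transcript.

    The candidate is fragment + ``ZZZ`` + fragment — the linker stands
    for a stretch of unknown length lost to the assembly error — scored
    against the shared subject. Fragments are ordered by where their
    hits start on the subject when ``subject_starts`` is given (a
    frameshifted fragment's ORF can begin upstream of the other fragment
    on the transcript, so transcript order alone can invert the protein
    order); otherwise by transcript coordinate. Accepted only when the
    merged E-value clears the improvement gate; on rejection the caller
    keeps the longer ORF as representative.
    """
    if orf1.transcript_id != orf2.transcript_id:
        raise ValueError("same-transcript merge requires ORFs of one transcript")
    if subject_starts is not None:
        keys = {orf1.orf_id: subject_starts[0], orf2.orf_id: subject_starts[1]}
        first, second = sorted(
            (orf1, orf2), key=lambda o: (keys[o.orf_id], o.nt_start)
        )
    else:
        first, second = (orf1, orf2) if orf1.nt_start <= orf2.nt_start else (orf2, orf1)
    merged_aa = first.aa_seq + LINKER + second.aa_seq
    hit = scorer.align("merged", merged_aa, subject_id, subject_aa)
    e_merged = hit.evalue if hit is not None else float("inf")
    accepted = merge_gate(e1, e2, e_merged, thresholds.merge_improvement_factor)
    return MergeDecision(
        kind="same_transcript",
        input_ids=(orf1.orf_id, orf2.orf_id),
        subject_id=subject_id,
        e1=e1,
        e2=e2,
        e_merged=e_merged,
        accepted=accepted,
        merged_aa=merged_aa if accepted else "",
    )


def longest_overlap(a: str, b: str, min_len: int) -> int:
    """Length of the longest exact suffix of ``a`` equal to a prefix of
    ``b``, or 0 if shorter than ``min_len``."""
    for n in range(min(len(a), len(b)), min_len - 1, -1):
        if a[-n:] == b[:n]:
            return n
    return 0


def merge_cross_transcript(
    id_a: str,
    aa_a: str,
    tid_a: str,
    e_a: float,
    id_b: str,
    aa_b: str,
    tid_b: str,
    e_b: float,
    subject_id: str,
    subject_aa: str,
    scaffold_map: Dict[str, str],
    scorer: PairwiseScorer,
    thresholds: Thresholds,
) -> Optional[MergeDecision]:
    """Attempt an overlap merge of ORFs/records from two transcripts.

    Eligible only when both parents map to the same scaffold and an exact
    suffix–prefix overlap of at least ``min_overlap_aa`` residues exists
    (longest such overlap, either orientation). Returns None when
    ineligible; otherwise a gated MergeDecision.
    """
    if tid_a == tid_b:
        raise ValueError("cross-transcript merge requires two different transcripts")
    scaf_a, scaf_b = scaffold_map.get(tid_a), scaffold_map.get(tid_b)
    if scaf_a is None or scaf_a != scaf_b:
        return None
    ov_ab = longest_overlap(aa_a, aa_b, thresholds.min_overlap_aa)
    ov_ba = longest_overlap(aa_b, aa_a, thresholds.min_overlap_aa)
    if ov_ab == 0 and ov_ba == 0:
        return None
    if ov_ab >= ov_ba:
        ov, merged_aa, overlap_aa = ov_ab, aa_a + aa_b[ov_ab:], aa_b[:ov_ab]
    else:
        ov, merged_aa, overlap_aa = ov_ba, aa_b + aa_a[ov_ba:], aa_a[:ov_ba]
    hit = scorer.align("merged", merged_aa, subject_id, subject_aa)
    e_merged = hit.evalue if hit is not None else float("inf")
    accepted = merge_gate(e_a, e_b, e_merged, thresholds.merge_improvement_factor)
    return MergeDecision(
        kind="cross_transcript",
        input_ids=(id_a, id_b),
        subject_id=subject_id,
        e1=e_a,
        e2=e_b,
        e_merged=e_merged,
        accepted=accepted,
        merged_aa=merged_aa if accepted else "",
        overlap_aa=overlap_aa,
        scaffold_id=scaf_a,
    )


def split_transcript(
    classification: TranscriptClassification,
    orfs: Dict[str, Orf],
) -> List[AnnotationRecord]:
    """Resolve a chimeric (MULTI_DIFF) transcript into one record per gene.

    Per distinct best subject the lowest-E ORF is kept; suffix letters
    ``_A``, ``_B``, ... are assigned by increasing ORF start coordinate.
    """
    if classification.category != MULTI_DIFF:
        raise ValueError("split requires a MULTI_DIFF classification")
    by_subject: Dict[str, Tuple[Orf, ProteinHit]] = {}
    for orf_id, hit in classification.orf_best.items():
        orf = orfs[orf_id]
        cur = by_subject.get(hit.subject_id)
        if cur is None or (hit.evalue, -hit.bitscore) < (cur[1].evalue, -cur[1].bitscore):
            by_subject[hit.subject_id] = (orf, hit)
    if len(by_subject) < 2:
        raise ValueError("split requires >= 2 distinct best subjects")
    parts = sorted(by_subject.values(), key=lambda t: (t[0].nt_start, t[0].orf_index))
    records = []
    for i, (orf, hit) in enumerate(parts):
        suffix = chr(ord("A") + i)
        records.append(
            AnnotationRecord(
                output_id=f"{classification.transcript_id}_{suffix}",
                aa_seq=orf.aa_seq,
                provenance="split_part",
                transcript_ids=(classification.transcript_id,),
                orf_ids=(orf.orf_id,),
                subject_id=hit.subject_id,
                evalue=hit.evalue,
            )
        )
    return records


def dedup_substrings(records: Sequence[AnnotationRecord]) -> List[AnnotationRecord]:
    """Remove records whose sequence is an exact substring of another.

    The longest survives; exact ties keep the lexicographically smallest
    output id. Survivors list the ids they absorbed.
    """
    ordered = sorted(records, key=lambda r: (-len(r.aa_seq), r.output_id))
    survivors: List[AnnotationRecord] = []
    for rec in ordered:
        host = next((s for s in survivors if rec.aa_seq in s.aa_seq), None)
        if host is not None:
            host.absorbed.append(rec.output_id)
        else:
            survivors.append(replace(rec, absorbed=list(rec.absorbed)))
    return survivors


def _chain_merge_same(
    tid: str,
    cls: TranscriptClassification,
    orfs: Dict[str, Orf],
    database: Optional[Dict[str, str]],
    scorer: Optional[PairwiseScorer],
    thresholds: Thresholds,
    merge_log: List[MergeDecision],
) -> AnnotationRecord:
    """Resolve a MULTI_SAME transcript: greedy linker merging of its
    significant ORFs in subject-coordinate order, re-gating after each
    join."""
    entries = sorted(
        ((orfs[oid], hit) for oid, hit in cls.orf_best.items()),
        key=lambda t: (t[1].s_start, t[0].nt_start, t[0].orf_index),
    )
    subject_id = entries[0][1].subject_id
    subject_aa = database.get(subject_id) if database else None
    n_accepted = 0
    cur_orf, cur_hit = entries[0]
    cur_aa, cur_e = cur_orf.aa_seq, cur_hit.evalue
    used = [cur_orf.orf_id]
    for nxt_orf, nxt_hit in entries[1:]:
        if subject_aa is None or scorer is None:
            continue  # cannot re-score: keep representatives separate below
        merged_aa = cur_aa + LINKER + nxt_orf.aa_seq
        hit = scorer.align("merged", merged_aa, subject_id, subject_aa)
        e_merged = hit.evalue if hit is not None else float("inf")
        accepted = merge_gate(cur_e, nxt_hit.evalue, e_merged, thresholds.merge_improvement_factor)
        merge_log.append(
            MergeDecision(
                kind="same_transcript",
                input_ids=(used[-1], nxt_orf.orf_id),
                subject_id=subject_id,
                e1=cur_e,
                e2=nxt_hit.evalue,
                e_merged=e_merged,
                accepted=accepted,
                merged_aa=merged_aa if accepted else "",
            )
        )
        if accepted:
            cur_aa, cur_e = merged_aa, e_merged
            used.append(nxt_orf.orf_id)
            n_accepted += 1
    if n_accepted > 0:
        return AnnotationRecord(
            output_id=tid,
            aa_seq=cur_aa,
            provenance="merged_linker",
            transcript_ids=(tid,),
            orf_ids=tuple(used),
            subject_id=subject_id,
            evalue=cur_e,
        )
    # no merge survived the gate: the longer ORF represents the transcript
    rep_orf, rep_hit = max(
        entries, key=lambda t: (len(t[0].aa_seq), -t[0].nt_start, -t[0].orf_index)
    )
    return AnnotationRecord(
        output_id=tid,
        aa_seq=rep_orf.aa_seq,
        provenance="representative",
        transcript_ids=(tid,),
        orf_ids=(rep_orf.orf_id,),
        subject_id=rep_hit.subject_id,
        evalue=rep_hit.evalue,
    )


def run_pipeline(
    transcripts: Sequence[SequenceRecord],
    genome_hits: Optional[Sequence[GenomeHit]] = None,
    genome: Optional[Sequence[SequenceRecord]] = None,
    protein_hits: Optional[Sequence[ProteinHit]] = None,
    database: Optional[Sequence[SequenceRecord]] = None,
    thresholds: Optional[Thresholds] = None,
    scorer_params: Optional[ScorerParams] = None,
) -> PipelineResult:
    """Run the full annotation flow and return records plus evidence trail.

    ``genome_hits`` may be supplied (e.g. from external BLASTN) or computed
    from ``genome`` with the built-in exact mapper. ``protein_hits``
    likewise may come from external BLASTP or be computed against
    ``database`` with the internal scorer. The database is also needed to
    re-score merge candidates; without it merges are not attempted.
    Deterministic given identical inputs and thresholds.
    """
    from .homology import map_transcripts_to_genome  # local to avoid cycle noise

    thresholds = thresholds or Thresholds()
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids in input")
    by_id = {t.id: t for t in transcripts}

    if genome_hits is None:
        if genome is None:
            raise ValueError("need genome_hits or a genome to filter against")
        genome_hits = map_transcripts_to_genome(transcripts, genome)
    else:
        dangling = {h.transcript_id for h in genome_hits} - set(ids)
        if dangling:
            raise ValueError(f"genome hits reference unknown transcripts: {sorted(dangling)[:5]}")

    clean, excluded, scaffold_map = genome_filter(ids, genome_hits, thresholds)

    # ORF extraction: three longest per clean transcript
    orf_map: Dict[str, Orf] = {}
    orfs_by_transcript: Dict[str, List[Orf]] = {}
    for tid in clean:
        selected = top_orfs(
            find_orfs(by_id[tid], min_aa=thresholds.orf_min_aa), k=thresholds.top_k_orfs
        )
        orfs_by_transcript[tid] = selected
        for o in selected:
            orf_map[o.orf_id] = o

    db_map = {r.id: r.residues for r in database} if database is not None else None
    scorer = None
    if db_map is not None:
        params = scorer_params or ScorerParams(
            m=max(sum(len(s) for s in db_map.values()), 1)
        )
        scorer = PairwiseScorer(params)

    if protein_hits is None:
        if scorer is None:
            raise ValueError("need protein_hits or a protein database to search")
        protein_hits = scorer.search(
            {o.orf_id: o.aa_seq for o in orf_map.values()}, db_map
        )
    else:
        dangling = {h.query_id for h in protein_hits} - set(orf_map)
        if dangling:
            raise ValueError(f"protein hits reference unknown ORFs: {sorted(dangling)[:5]}")

    hits_by_transcript: Dict[str, List[ProteinHit]] = {tid: [] for tid in clean}
    for h in protein_hits:
        tid = orf_map[h.query_id].transcript_id
        hits_by_transcript[tid].append(h)

    classifications: Dict[str, TranscriptClassification] = {}
    merge_log: List[MergeDecision] = []
    records: List[AnnotationRecord] = []
    unknown: List[str] = []
    n_split_records = 0

    for tid in clean:
        cls = classify_transcript(tid, hits_by_transcript[tid], thresholds)
        classifications[tid] = cls
        if cls.category == NO_MATCH:
            unknown.append(tid)
        elif cls.category == UNIQUE:
            orf_id, hit = next(iter(cls.orf_best.items()))
            orf = orf_map[orf_id]
            records.append(
                AnnotationRecord(
                    output_id=tid,
                    aa_seq=orf.aa_seq,
                    provenance="representative",
                    transcript_ids=(tid,),
                    orf_ids=(orf.orf_id,),
                    subject_id=hit.subject_id,
                    evalue=hit.evalue,
                )
            )
        elif cls.category == MULTI_SAME:
            records.append(
                _chain_merge_same(tid, cls, orf_map, db_map, scorer, thresholds, merge_log)
            )
        else:  # MULTI_DIFF
            parts = split_transcript(cls, orf_map)
            n_split_records += len(parts)
            records.extend(parts)

    n_unique = sum(1 for c in classifications.values() if c.category == UNIQUE)
    n_same = sum(1 for c in classifications.values() if c.category == MULTI_SAME)
    n_diff = sum(1 for c in classifications.values() if c.category == MULTI_DIFF)

    # cross-transcript overlap merges among single-gene records sharing a
    # best subject and a scaffold
    cross_accepted = 0
    if scorer is not None and db_map is not None:
        groups: Dict[Tuple[str, str], List[AnnotationRecord]] = {}
        rest: List[AnnotationRecord] = []
        for rec in records:
            if rec.provenance in ("representative", "merged_linker") and rec.subject_id in db_map:
                key = (scaffold_map[rec.transcript_ids[0]], rec.subject_id)
                groups.setdefault(key, []).append(rec)
            else:
                rest.append(rec)
        merged_records: List[AnnotationRecord] = []
        for key in sorted(groups):
            pool = sorted(groups[key], key=lambda r: r.output_id)
            i = 0
            while i < len(pool):
                a = pool[i]
                j = i + 1
                merged_here = False
                while j < len(pool):
                    b = pool[j]
                    decision = merge_cross_transcript(
                        a.output_id, a.aa_seq, a.transcript_ids[0], a.evalue,
                        b.output_id, b.aa_seq, b.transcript_ids[0], b.evalue,
                        key[1], db_map[key[1]], scaffold_map, scorer, thresholds,
                    )
                    if decision is not None:
                        merge_log.append(decision)
                    if decision is not None and decision.accepted:
                        cross_accepted += 1
                        merged = AnnotationRecord(
                            output_id=f"{a.output_id}+{b.output_id}",
                            aa_seq=decision.merged_aa,
                            provenance="cross_merged",
                            transcript_ids=a.transcript_ids + b.transcript_ids,
                            orf_ids=a.orf_ids + b.orf_ids,
                            subject_id=key[1],
                            evalue=decision.e_merged,
                        )
                        pool.pop(j)
                        pool[i] = merged
                        a = merged
                        merged_here = True
                    else:
                        j += 1
                if not merged_here:
                    i += 1
            merged_records.extend(pool)
        records = rest + merged_records
        records.sort(key=lambda r: r.output_id)

    pre_dedup = len(records)
    final = dedup_substrings(records)

    counts = {
        "input_transcripts": len(ids),
        "excluded": len(excluded),
        "clean": len(clean),
        "no_match": len(unknown),
        "unique": n_unique,
        "multi_same": n_same,
        "multi_diff": n_diff,
        "split_records": n_split_records,
        "merges_attempted": len(merge_log),
        "same_merges_accepted": sum(
            1 for d in merge_log if d.accepted and d.kind == "same_transcript"
        ),
        "cross_merges_accepted": cross_accepted,
        "records_pre_dedup": pre_dedup,
        "dedup_removed": pre_dedup - len(final),
        "final_records": len(final),
    }
    # accounting identity: every single-gene transcript contributes one
    # record, every chimera one per gene, minus records fused across
    # transcripts
    assert pre_dedup == n_unique + n_same + n_split_records - cross_accepted

    return PipelineResult(
        records=final,
        classifications=classifications,
        merge_log=merge_log,
        excluded=excluded,
        unknown=unknown,
        scaffold_map=scaffold_map,
        counts=counts,
    )
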