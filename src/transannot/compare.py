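"""Reciprocal comparison of two annotation protein sets.

Answers, in both directions, "which proteins of one annotation are not
covered by the other?" — the question behind cross-validating a
transcriptome-derived protein set against an independent genome
annotation. Matching is directional best-hit at an E-value cutoff
(default 1e-10), deliberately *not* reciprocal-best-hit orthology: any
alignment at the cutoff counts as coverage.

Proteins dominated by internal repeats are flagged (fraction of the
sequence covered by exact 12-mers occurring more than once, threshold
0.5). The flag is reported only, never used to filter — most proteins
missed by one annotation or the other tend to be repeat-rich (often
transposable elements), and the flag lets users triage them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .homology import PairwiseScorer, ProteinHit, ScorerParams, best_hit_per_query
from .seqio import SequenceRecord

__all__ = ["ComparisonReport", "compare_annotations", "repeat_fraction"]

REPEAT_K = 12
REPEAT_THRESHOLD = 0.5


@dataclass
class ComparisonReport:
    set_a_name: str
    set_b_name: str
    cutoff: float
    missing_in_b: List[str]  # A-proteins with no hit in B at the cutoff
    missing_in_a: List[str]
    matched_a: Dict[str, Tuple[str, float]]  # a_id -> (best b_id, evalue)
    matched_b: Dict[str, Tuple[str, float]]
    repeat_flags: Dict[str, bool] = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.set_a_name}: {len(self.matched_a)} matched, "
            f"{len(self.missing_in_b)} missing in {self.set_b_name}; "
            f"{self.set_b_name}: {len(self.matched_b)} matched, "
            f"{len(self.missing_in_a)} missing in {self.set_a_name} "
            f"(E-value cutoff {self.cutoff:g})"
        )


def repeat_fraction(aa_seq: str, k: int = REPEAT_K) -> float:
    """Fraction of positions covered by exact k-mers occurring >1 time
    within the sequence."""
    if len(aa_seq) < k:
        return 0.0
    counts: Dict[str, int] = {}
    for i in range(len(aa_seq) - k + 1):
        kmer = aa_seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    covered = [False] * len(aa_seq)
    for i in range(len(aa_seq) - k + 1):
        if counts[aa_seq[i : i + k]] > 1:
            for j in range(i, i + k):
                covered[j] = True
    return sum(covered) / len(aa_seq)


def _missing_and_matched(
    queries: Sequence[SequenceRecord],
    hits: Sequence[ProteinHit],
    cutoff: float,
) -> Tuple[List[str], Dict[str, Tuple[str, float]]]:
    best = best_hit_per_query(hits)
    missing, matched = [], {}
    for rec in queries:
        hit = best.get(rec.id)
        if hit is None or hit.evalue > cutoff:
            missing.append(rec.id)
        else:
            matched[rec.id] = (hit.subject_id, hit.evalue)
    return missing, matched


def compare_annotations(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    cutoff: float = 1e-10,
    hits_ab: Optional[Sequence[ProteinHit]] = None,
    hits_ba: Optional[Sequence[ProteinHit]] = None,
    set_a_name: str = "A",
    set_b_name: str = "B",
    scorer_params: Optional[ScorerParams] = None,
) -> ComparisonReport:
    """Compare two protein sets; a protein is *missing* from the other set
    when its best cross-hit has E-value above the cutoff or no hit exists.

    Evidence may be supplied as two pre-computed hit tables (A-vs-B and
    B-vs-A, e.g. external BLASTP outfmt 6); otherwise both searches run
    through the internal scorer.
    """
    for name, recs in ((set_a_name, set_a), (set_b_name, set_b)):
        ids = [r.id for r in recs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ids in set {name}")
    a_map = {r.id: r.residues for r in set_a}
    b_map = {r.id: r.residues for r in set_b}
    for hits, qmap, smap, label in (
        (hits_ab, a_map, b_map, f"{set_a_name}-vs-{set_b_name}"),
        (hits_ba, b_map, a_map, f"{set_b_name}-vs-{set_a_name}"),
    ):
        if hits is not None:
            bad = {h.query_id for h in hits} - set(qmap) | ({h.subject_id for h in hits} - set(smap))
            if bad:
                raise ValueError(f"{label} evidence references unknown ids: {sorted(bad)[:5]}")

    if hits_ab is None or hits_ba is None:
        scorer_ab = PairwiseScorer(
            scorer_params or ScorerParams(m=sum(len(s) for s in b_map.values()))
        )
        scorer_ba = PairwiseScorer(
            scorer_params or ScorerParams(m=sum(len(s) for s in a_map.values()))
        )
        if hits_ab is None:
            hits_ab = scorer_ab.search(a_map, b_map)
        if hits_ba is None:
            hits_ba = scorer_ba.search(b_map, a_map)

    missing_in_b, matched_a = _missing_and_matched(set_a, hits_ab, cutoff)
    missing_in_a, matched_b = _missing_and_matched(set_b, hits_ba, cutoff)
    repeat_flags = {
        rec.id: repeat_fraction(rec.residues) >= REPEAT_THRESHOLD
        for rec in list(set_a) + list(set_b)
    }
    return ComparisonReport(
        set_a_name=set_a_name,
        set_b_name=set_b_name,
        cutoff=cutoff,
        missing_in_b=missing_in_b,
        missing_in_a=missing_in_a,
        matched_a=matched_a,
        matched_b=matched_b,
        repeat_flags=repeat_flags,
    )
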