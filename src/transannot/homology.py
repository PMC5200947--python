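"""Homology evidence: hit tables, an internal protein aligner, and a
nucleotide genome mapper.

The pipeline consumes BLAST-style tabular evidence (outfmt 6, 12 columns).
Users with an external BLAST+ installation can supply hit tables directly;
otherwise the :class:`PairwiseScorer` computes local protein alignments
(Smith–Waterman, affine gaps, BLOSUM62) and converts raw scores to
bitscores and E-values through the Karlin–Altschul relations

    S' = (lambda * S - ln K) / ln 2,        E = m * n * 2**(-S')

with ``m`` the effective database length and ``n`` the query length.
These reproduce the *scale* of BLAST statistics well enough for the
pipeline's threshold logic; exact BLAST parity (seeding heuristics,
composition-based statistics) is out of scope.

The merge linker residue ``Z`` scores 0 against every residue: it marks a
gap of unknown length and must neither reward nor punish a merged
alignment.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "ProteinHit",
    "GenomeHit",
    "ScorerParams",
    "HitTableError",
    "parse_hit_table",
    "write_hit_table",
    "best_hit_per_query",
    "PairwiseScorer",
    "bitscore_from_raw",
    "evalue_from_bitscore",
    "map_transcripts_to_genome",
]


@dataclass(frozen=True)
class ProteinHit:
    """One protein-vs-protein alignment record (outfmt 6 line)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class GenomeHit:
    """One transcript-vs-genome alignment record."""

    transcript_id: str
    scaffold_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    t_start: int
    t_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


class HitTableError(ValueError):
    pass


def parse_hit_table(path: str | os.PathLike, kind: str = "protein"):
    """Parse a 12-column tab-separated hit table (BLAST outfmt 6).

    ``kind`` selects the record type: "protein" -> ProteinHit (ORF vs
    protein database), "genome" -> GenomeHit (transcript vs scaffold).
    Order is preserved; E-values like ``2e-175`` and ``0.0`` are accepted.
    """
    cls = ProteinHit if kind == "protein" else GenomeHit
    hits = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise HitTableError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            try:
                hits.append(
                    cls(
                        cols[0],
                        cols[1],
                        float(cols[2]),
                        int(cols[3]),
                        int(cols[4]),
                        int(cols[5]),
                        int(cols[6]),
                        int(cols[7]),
                        int(cols[8]),
                        int(cols[9]),
                        float(cols[10]),
                        float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise HitTableError(f"{path}:{lineno}: unparseable numeric field ({exc})") from None
    return hits


def _format_evalue(e: float) -> str:
    return "0.0" if e == 0 else f"{e:.2e}"


def write_hit_table(hits: Iterable[ProteinHit | GenomeHit], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for h in hits:
            fields = list(h.__dict__.values())
            out.write(
                "\t".join(
                    [
                        fields[0],
                        fields[1],
                        f"{fields[2]:.2f}",
                        *[str(v) for v in fields[3:10]],
                        _format_evalue(fields[10]),
                        f"{fields[11]:.1f}",
                    ]
                )
                + "\n"
            )


def best_hit_per_query(hits: Iterable[ProteinHit]) -> Dict[str, ProteinHit]:
    """Best hit per query: lowest E-value, ties by highest bitscore, then
    first occurrence."""
    best: Dict[str, ProteinHit] = {}
    for h in hits:
        q = h.query_id
        cur = best.get(q)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[q] = h
    return best


# ---------------------------------------------------------------------------
# Internal protein aligner


@dataclass
class ScorerParams:
    """Scoring model: substitution matrix, affine gap penalties and
    Karlin–Altschul constants.

    Defaults are the standard gapped BLASTP constants (BLOSUM62, gap
    open 11, extend 1, lambda 0.267, K 0.041). A gap of length k costs
    ``gap_open + k * gap_extend``. ``m`` is the effective database length
    in residues; ``n`` defaults to the query length at scoring time.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041
    m: int = 1
    n: Optional[int] = None

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.m < 1:
            raise ValueError("effective database length m must be >= 1")


def bitscore_from_raw(raw: float, params: ScorerParams) -> float:
    """Normalized (bit) score from a raw alignment score."""
    return (params.lam * raw - math.log(params.K)) / math.log(2.0)


def evalue_from_bitscore(bitscore: float, params: ScorerParams, query_len: Optional[int] = None) -> float:
    """Expected number of chance alignments at this score: m * n * 2^-S'."""
    n = query_len if query_len is not None else (params.n or 1)
    log_e = math.log(params.m) + math.log(n) - bitscore * math.log(2.0)
    if log_e < -700:
        return 0.0
    return math.exp(log_e)


def _linker_neutral_matrix(name: str):
    mat = substitution_matrices.load(name).copy()
    if "Z" in mat.alphabet:
        for a in mat.alphabet:
            mat["Z", a] = 0.0
            mat[a, "Z"] = 0.0
    return mat


class PairwiseScorer:
    """Local protein alignment with BLAST-style statistics.

    A drop-in stand-in for a BLASTP search at small scale: exact
    Smith–Waterman rather than seed-and-extend, so scores are optimal.
    For database searches an exact k-mer prefilter keeps the number of
    dynamic-programming calls proportional to the number of true
    homolog pairs.
    """

    def __init__(self, params: Optional[ScorerParams] = None):
        self.params = params or ScorerParams()
        self._matrix = _linker_neutral_matrix(self.params.matrix)
        self._aligner = PairwiseAligner(
            mode="local",
            substitution_matrix=self._matrix,
            # first gap position costs open+extend, each further one extend
            open_gap_score=-(self.params.gap_open + self.params.gap_extend),
            extend_gap_score=-self.params.gap_extend,
        )

    def raw_score(self, query: str, subject: str) -> int:
        if not query or not subject:
            raise ValueError("empty sequence")
        return int(round(self._aligner.score(query, subject)))

    def align(self, query_id: str, query: str, subject_id: str, subject: str) -> Optional[ProteinHit]:
        """Optimal local alignment as a ProteinHit, or None when no
        positive-scoring alignment exists."""
        raw = self.raw_score(query, subject)
        if raw <= 0:
            return None
        aln = next(iter(self._aligner.align(query, subject)))
        (q0, q1) = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
        (s0, s1) = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
        matches = mismatches = cols = 0
        for (qa, qb), (sa, sb) in zip(aln.aligned[0], aln.aligned[1]):
            for i in range(qb - qa):
                cols += 1
                if query[qa + i] == subject[sa + i]:
                    matches += 1
                else:
                    mismatches += 1
        gap_cols = (q1 - q0) + (s1 - s0) - 2 * cols
        gap_opens = max(len(aln.aligned[0]) - 1, 0)
        align_len = cols + gap_cols
        bits = bitscore_from_raw(raw, self.params)
        ev = evalue_from_bitscore(bits, self.params, len(query))
        return ProteinHit(
            query_id=query_id,
            subject_id=subject_id,
            pct_identity=100.0 * matches / max(cols, 1),
            align_len=align_len,
            mismatches=mismatches,
            gap_opens=gap_opens,
            q_start=q0 + 1,
            q_end=q1,
            s_start=s0 + 1,
            s_end=s1,
            evalue=ev,
            bitscore=bits,
        )

    def search(
        self,
        queries: Dict[str, str],
        subjects: Dict[str, str],
        k: int = 4,
        min_shared_kmers: int = 4,
    ) -> List[ProteinHit]:
        """All-vs-all search with an exact k-mer prefilter.

        A query/subject pair is aligned only when it shares at least
        ``min_shared_kmers`` exact amino-acid k-mers — cheap, and at 10–20%
        sequence divergence true homologs share dozens while unrelated
        pairs share none. Results are sorted by (query, E-value).
        """
        index: Dict[str, set] = {}
        for sid, sseq in subjects.items():
            for i in range(len(sseq) - k + 1):
                index.setdefault(sseq[i : i + k], set()).add(sid)
        hits: List[ProteinHit] = []
        for qid in sorted(queries):
            qseq = queries[qid]
            counts: Dict[str, int] = {}
            for i in range(len(qseq) - k + 1):
                for sid in index.get(qseq[i : i + k], ()):
                    counts[sid] = counts.get(sid, 0) + 1
            for sid in sorted(s for s, c in counts.items() if c >= min_shared_kmers):
                hit = self.align(qid, qseq, sid, subjects[sid])
                if hit is not None:
                    hits.append(hit)
        hits.sort(key=lambda h: (h.query_id, h.evalue, -h.bitscore, h.subject_id))
        return hits


# ---------------------------------------------------------------------------
# Nucleotide genome mapper

# megablast-like ungapped constants (match +1 / mismatch -2)
_NT_LAMBDA = 1.28
_NT_K = 0.46


def _nt_bits(match_len: int) -> float:
    return (_NT_LAMBDA * match_len - math.log(_NT_K)) / math.log(2.0)


def map_transcripts_to_genome(
    transcripts: Sequence[SequenceRecord],
    genome: Sequence[SequenceRecord],
    k: int = 31,
) -> List[GenomeHit]:
    """Map transcripts onto genome scaffolds by exact-match seed and extend.

    Finds, per transcript, maximal exact matches seeded by shared k-mers
    (both orientations tried) and reports each as a GenomeHit whose
    bitscore follows the ungapped nucleotide Karlin–Altschul model. This
    fills the role a BLASTN search plays upstream of the genome filter:
    a transcript drawn from the genome produces a long exact run and a
    large bitscore, while a sequence from another organism produces no
    seed at all. It is not a spliced or mismatch-tolerant aligner.
    """
    index: Dict[str, List[Tuple[int, int]]] = {}
    for si, scaf in enumerate(genome):
        s = scaf.residues
        for i in range(len(s) - k + 1):
            index.setdefault(s[i : i + k], []).append((si, i))

    genome_len = sum(len(g) for g in genome)
    hits: List[GenomeHit] = []
    for rec in transcripts:
        best = None  # (match_len, si, t0, g0, orientation)
        for orientation, tseq in (("+", rec.residues), ("-", reverse_complement(rec.residues))):
            i = 0
            while i + k <= len(tseq):
                matches = index.get(tseq[i : i + k])
                if not matches:
                    i += k
                    continue
                si, gpos = matches[0]
                gseq = genome[si].residues
                # extend exact match left and right
                left = 0
                while i - left - 1 >= 0 and gpos - left - 1 >= 0 and tseq[i - left - 1] == gseq[gpos - left - 1]:
                    left += 1
                right = k
                while i + right < len(tseq) and gpos + right < len(gseq) and tseq[i + right] == gseq[gpos + right]:
                    right += 1
                mlen = left + right
                if best is None or mlen > best[0]:
                    best = (mlen, si, i - left, gpos - left, orientation)
                i = i + right  # skip past the extended match
        if best is None:
            continue
        mlen, si, t0, g0, orientation = best
        bits = _nt_bits(mlen)
        if orientation == "+":
            t_start, t_end = t0 + 1, t0 + mlen
        else:  # coordinates back on the forward transcript
            t_start, t_end = len(rec) - (t0 + mlen) + 1, len(rec) - t0
        ev = math.exp(
            min(math.log(genome_len) + math.log(len(rec)) - bits * math.log(2.0), 700)
        )
        if ev < 1e-300:
            ev = 0.0
        hits.append(
            GenomeHit(
                transcript_id=rec.id,
                scaffold_id=genome[si].id,
                pct_identity=100.0,
                align_len=mlen,
                mismatches=0,
                gap_opens=0,
                t_start=t_start,
                t_end=t_end,
                s_start=g0 + 1,
                s_end=g0 + mlen,
                evalue=ev,
                bitscore=bits,
            )
        )
    return hits
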