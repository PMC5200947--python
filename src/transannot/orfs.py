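"""Six-frame ORF enumeration and longest-ORF selection.

An ORF here is a maximal stop-free translated stretch (stop-to-stop; no
start codon required), the convention of EMBOSS getorf's default mode.
De novo assembled transcripts routinely lack complete 5' ends, so
requiring ATG would discard real coding fragments; homology filtering
downstream removes spurious stretches instead.

Coordinates are 1-based inclusive on the *forward* strand of the input
transcript, with ``nt_start <= nt_end`` always; the ``strand`` field
carries direction. The terminal stop codon is excluded from both the
span and the translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

from .seqio import SequenceRecord, reverse_complement, translate, write_fasta

__all__ = ["Orf", "find_orfs", "top_orfs", "write_orf_fasta"]


@dataclass(frozen=True)
class Orf:
    transcript_id: str
    orf_index: int
    strand: str  # "forward" | "reverse"
    frame: int  # 1 | 2 | 3 (on its own strand)
    nt_start: int  # 1-based inclusive, forward transcript coordinates
    nt_end: int
    aa_seq: str

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}_ORF_{self.orf_index}"

    @property
    def coord_label(self) -> str:
        """Display form: forward low-high, reverse high-low."""
        if self.strand == "forward":
            return f"fwd: {self.nt_start}-{self.nt_end}"
        return f"reverse: {self.nt_end}-{self.nt_start}"

    def __len__(self) -> int:
        return len(self.aa_seq)


def _frame_stretches(aa_full: str, min_aa: int):
    """Yield (aa_start, aa_end_exclusive, aa_seq) of stop-free stretches."""
    start = 0
    for i, ch in enumerate(aa_full + "*"):
        if ch == "*":
            if i - start >= min_aa:
                yield start, i, aa_full[start:i]
            start = i + 1


def find_orfs(record: SequenceRecord, min_aa: int = 30) -> List[Orf]:
    """Enumerate all ORFs of length >= ``min_aa`` across six frames.

    Enumeration order: forward-strand ORFs by start position (then frame),
    then reverse-strand ORFs by start position on the reverse complement;
    ``orf_index`` is assigned in that order starting at 1.
    """
    if record.alphabet != "nt":
        raise ValueError(f"record {record.id!r} is not nucleotide")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = record.residues
    L = len(seq)
    found = []  # (strand_order, strand_start, frame, orf fields)
    for strand in ("forward", "reverse"):
        s = seq if strand == "forward" else reverse_complement(seq)
        for offset in range(3):
            if L - offset < 3:
                continue
            aa_full = translate(s, offset)
            for aa_s, aa_e, aa_seq in _frame_stretches(aa_full, min_aa):
                # span on this strand, 1-based inclusive, stop excluded
                ss = offset + 3 * aa_s + 1
                se = offset + 3 * aa_e
                if strand == "forward":
                    nt_start, nt_end = ss, se
                else:
                    nt_start, nt_end = L - se + 1, L - ss + 1
                found.append((strand != "forward", ss, offset + 1, strand, nt_start, nt_end, aa_seq))
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        Orf(record.id, idx, strand, frame, nt_start, nt_end, aa_seq)
        for idx, (_, _, frame, strand, nt_start, nt_end, aa_seq) in enumerate(found, 1)
    ]


def top_orfs(orfs: Iterable[Orf], k: int = 3) -> List[Orf]:
    """The ``k`` longest ORFs of one transcript.

    Ties broken forward-before-reverse, then smaller nt_start, then smaller
    orf_index. Returns fewer than ``k`` when fewer exist.
    """
    orfs = list(orfs)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len({o.transcript_id for o in orfs}) > 1:
        raise ValueError("top_orfs requires ORFs from a single transcript")
    orfs.sort(key=lambda o: (-len(o.aa_seq), o.strand != "forward", o.nt_start, o.orf_index))
    return orfs[:k]


def write_orf_fasta(orfs: Iterable[Orf], path: str) -> None:
    """Write ORF translations as the query FASTA for a protein search.

    Headers encode transcript, strand, frame and span so external hit
    tables can be traced back to coordinates.
    """
    records = [
        SequenceRecord(
            o.orf_id,
            o.aa_seq,
            f"strand={o.strand} frame={o.frame} {o.coord_label}",
            alphabet="aa",
        )
        for o in orfs
    ]
    write_fasta(records, path)
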