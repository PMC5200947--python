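"""Sequence I/O and translation primitives.

FASTA is the only format this module speaks: nucleotide transcriptomes and
genome scaffolds on one side, amino-acid ORF/protein sets on the other.
Records are validated on read against a declared alphabet; the amino-acid
alphabet additionally admits ``Z``, the linker residue inserted between
merged ORF fragments (it marks a gap of unknown length and must never be
treated as a standard residue downstream).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "translate",
    "CODON_TABLE",
    "NT_ALPHABET",
    "AA_ALPHABET",
]

NT_ALPHABET = frozenset("ACGTN")
# 20 standard residues + X (unknown) + * (stop, writer-side only) + Z (merge linker)
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*Z")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (translation table 1), codons enumerated in TCAG order.
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    b1 + b2 + b3: _AA_ORDER[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}


class FastaError(ValueError):
    """Malformed FASTA input (message carries file and record context)."""


@dataclass
class SequenceRecord:
    """One FASTA record.

    ``id`` is the first whitespace-delimited token of the header (matching
    the transcript-id style of de novo assemblers, e.g. ``C20727_G1_I1``);
    the remainder of the header line is kept verbatim in ``description``.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nt"  # "nt" or "aa"

    def __len__(self) -> int:
        return len(self.residues)


def _validate_record(rec: SequenceRecord, source: str) -> None:
    if not rec.id:
        raise FastaError(f"{source}: empty sequence id")
    if any(c.isspace() for c in rec.id):
        raise FastaError(f"{source}: id contains whitespace: {rec.id!r}")
    if not rec.residues:
        raise FastaError(f"{source}: record {rec.id!r} has an empty sequence")
    allowed = NT_ALPHABET if rec.alphabet == "nt" else AA_ALPHABET
    bad = set(rec.residues) - allowed
    if bad:
        raise FastaError(
            f"{source}: record {rec.id!r} has characters outside the "
            f"{rec.alphabet} alphabet: {sorted(bad)}"
        )


def read_fasta(path: str | os.PathLike, alphabet: str = "nt") -> List[SequenceRecord]:
    """Read an entire FASTA file into validated records, order preserved.

    Lower-case residues are upper-cased and, for nucleotide input, ``U`` is
    mapped to ``T``. Duplicate ids and characters outside the declared
    alphabet are rejected.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    with open(path) as handle:
        # SimpleFastaParser silently skips leading junk; reject it explicitly.
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(f"{path}: sequence data before first '>' header")
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")
        handle.seek(0)
        records = []
        seen = set()
        for header, seq in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            rec_id = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            seq = seq.upper()
            if alphabet == "nt":
                seq = seq.replace("U", "T")
            rec = SequenceRecord(rec_id, seq, desc, alphabet)
            _validate_record(rec, path)
            if rec.id in seen:
                raise FastaError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            records.append(rec)
    if not records:
        raise FastaError(f"{path}: no records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``width`` columns."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, offset: int = 0) -> str:
    """Translate a nucleotide string starting at ``offset`` (0, 1 or 2).

    Standard genetic code; stop codons render ``*``; a trailing partial
    codon is dropped; codons containing ``N`` render ``X``.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset}")
    if len(seq) - offset < 3:
        raise ValueError(
            f"sequence too short to translate: {len(seq)} nt at offset {offset}"
        )
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None:
            if set(codon) <= NT_ALPHABET:
                aa = "X"  # ambiguity from N
            else:
                raise ValueError(f"invalid codon {codon!r} at position {i}")
        out.append(aa)
    return "".join(out)
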