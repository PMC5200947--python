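"""Six-frame ORF extraction and the internal aligner's statistics.

Finds the ORFs of a transcript carrying two coding stretches, then shows
how a local alignment's raw score becomes a bitscore and E-value through
the Karlin-Altschul relations.
"""

from transannot import SequenceRecord, find_orfs, top_orfs
from transannot.homology import PairwiseScorer, ScorerParams

# two repetitive coding stretches separated by an in-frame stop
seq = ("ATG" + "GCTGAAACCCTGGTGAAA" * 6 + "TAA" + "ATG" + "CCGGATTTTGGTCAT" * 7 + "TGA")
rec = SequenceRecord("demo_transcript", seq, "", "nt")

orfs = find_orfs(rec, min_aa=20)
print(f"{len(orfs)} ORFs of >=20 aa in six frames:")
for o in top_orfs(orfs, k=3):
    print(f"  {o.orf_id}  {o.coord_label}  {len(o.aa_seq)} aa  {o.aa_seq[:25]}...")
# Coordinates are 1-based on the forward strand; reverse-strand ORFs
# display high-to-low. Note the two longest ORFs here are *antisense*
# chance ORFs — low-complexity sequence rarely hits a stop codon in any
# frame, which is exactly why the annotation flow trusts homology
# significance, not ORF length alone, to pick the real coding frame.

scorer = PairwiseScorer(ScorerParams(m=1_000_000))  # m: effective database size
query = top_orfs(orfs, k=1)[0].aa_seq
hit = scorer.align("query", query, "subject", query)
print(f"\nself-alignment of the longest ORF ({len(query)} aa):")
print(f"  raw score -> bitscore {hit.bitscore:.1f}, E-value {hit.evalue:.2e}")
# E = m * n * 2^-bitscore: the expected number of chance alignments this
# good in a database of m residues; values far below 1e-8 count as
# significant in the annotation flow.
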