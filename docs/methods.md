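# Methods

## Model and assumptions

The pipeline treats the transcriptome as the primary evidence for the gene
space of a genome. Its core assumptions:

- A transcript that cannot be aligned to the genome assembly does not
  belong to the organism (or falls in an assembly gap) and is excluded
  rather than annotated. The filter is a bitscore threshold on the best
  transcript-vs-genome alignment, not a coverage requirement.
- Real coding regions reveal themselves through protein homology, not
  through ORF length: ORFs are enumerated stop-to-stop without requiring a
  start codon (de novo transcripts are frequently 5'-truncated), and only
  homology-significant ORFs drive decisions. Limiting each transcript to
  its three longest ORFs bounds work and suffices because a transcript
  rarely encodes more than two genes.
- Two ORFs of one transcript matching the same database protein indicate a
  broken coding region (an indel or frameshift from sequencing or
  assembly), not two paralogs: at stringent E-value cutoffs the chance of
  two independent loci on one transcript hitting the same accession is
  negligible.
- Two transcripts mapping to one scaffold whose ORFs overlap exactly at
  the amino-acid level are fragments of one gene the assembler failed to
  join.
- One transcript matching two different proteins in non-overlapping ORFs
  is a chimera and must contribute one annotation record per gene.

Every repair is gated by the same evidence test: the merged fragment must
align to the shared subject with an E-value better than the best
fragment's by a configurable multiplicative factor. A merge that does not
make the evidence *much* stronger is refused, and the longer fragment
represents the transcript.

## Thresholds

| parameter | default | units | role |
|---|---|---|---|
| `genome_bitscore_min` | 75 | bits | genome filter, inclusive |
| `protein_evalue_max` | 1e-8 | E-value | significance gate (with bitscore, conjunctive) |
| `protein_bitscore_min` | 60 | bits | significance gate |
| `merge_improvement_factor` | 1e-3 | — | merged E ≤ min(e1,e2) × factor |
| `min_overlap_aa` | 7 | residues | exact cross-transcript overlap |
| `orf_min_aa` | 30 | residues | minimum reported ORF |
| `top_k_orfs` | 3 | — | ORFs retained per transcript |
| `comparison_evalue_max` | 1e-10 | E-value | annotation-set comparison cutoff |

The two significance criteria (E-value and bitscore) are applied
conjunctively — the conservative intersection of the two conventions in
circulation; either can be relaxed by configuration. The genome-filter
boundary is inclusive (a hit at exactly 75 bits passes). The improvement
factor 1e-3 is loose relative to real repaired breaks, which typically
improve by tens of orders of magnitude; it exists to refuse merges whose
combined alignment is no better than its parts.

## Alignment statistics

The internal scorer computes exact Smith–Waterman local alignments
(affine gaps: a gap of length k costs `gap_open + k·gap_extend`, defaults
11 + k) under BLOSUM62, via Biopython's PairwiseAligner. Raw scores map to
bitscores and E-values through the Karlin–Altschul relations with the
standard gapped constants λ = 0.267, K = 0.041; the effective database
length m is the total residue count of the database actually searched.
These reproduce the scale of BLAST statistics — enough for threshold
logic — but not BLAST's composition-based adjustments, so E-values from
external BLAST tables and from the internal scorer should not be mixed
within one run's gate decisions.

The linker residue `Z` scores 0 against every residue, including itself:
it marks a gap of unknown length between merged fragments and must
neither reward nor penalise the merged alignment beyond the gap cost the
aligner already charges.

Database searches are pre-filtered by exact amino-acid 4-mers (a pair is
aligned only when it shares ≥ 4 of them). At 10–20% divergence true
homologs share dozens of 4-mers; unrelated sequences of these lengths
share almost none. The filter bounds the number of dynamic-programming
calls, not their exactness.

The transcript-vs-genome mapper is exact-match seed-and-extend (31-mer
seeds, both orientations) with megablast-like ungapped constants
(λ = 1.28, K = 0.46), so a genome-derived transcript scores far above the
75-bit cutoff from any ≥ 42 nt exact run, while foreign sequence finds no
seed. It is not splice- or mismatch-aware; with real (polymorphic, spliced)
data, supply a BLASTN/minimap2-derived hit table instead.

## Merge mechanics

Within a transcript, significant same-subject ORFs are merged greedily in
order of their hits' subject-start coordinates, re-gating after each join.
Subject order is used rather than transcript order because the
frameshifted fragment's ORF often extends upstream through untranslated
or out-of-frame sequence and can *start* before the other fragment's ORF,
so transcript coordinates can invert the protein order and doom the
merged alignment; where subject coordinates are unavailable the 5'-most
ORF comes first. Cross-transcript merges require a shared scaffold and an
exact suffix–prefix overlap (longest overlap wins, both orientations
tried); records may chain through successive accepted merges.

## The synthetic study

`simulate()` emulates the input ecosystem at toy scale: genes with random
proteins (100–300 aa) and uniformly chosen synonymous codons are placed on
scaffolds with random intergenic spacers; the database holds each protein
mutated at 10% per residue (a typical within-family cross-species
distance); transcripts add 0–300 nt random UTRs. Artifacts are planted at
the rates observed in real de novo assemblies: 5% broken transcripts
(half as one transcript with an internal frameshifting deletion, half as
two transcripts retaining an 8–15 aa exact overlap), 3% chimeras (two
CDSs joined by a spacer with stops in all six frames), 10% contaminants
(random sequence with no genome locus), 5% redundant exact substrings.
Break points leave ≥ 40 residues per fragment — the method targets
sizable fragment pairs, and much smaller fragments cannot clear the
bitscore-60 gate at 10% divergence even in principle.

Planted artifacts are validated to actually exhibit their defining ORF
structure (both fragments, or both fused genes, among the transcript's
three longest ORFs); the stochastic padding or split point is redrawn
when a chance ORF from untranslated or antisense sequence buries a
fragment, and for chimeras one CDS copy may be synonymously re-encoded
(the other stays genome-exact so the genome filter still passes). Without
this, a truth label would occasionally describe an artifact the transcript
does not contain.

What the generator does **not** emulate: introns and splicing, codon-usage
bias, sequencing error within reads, expression levels, genuine paralogy,
and reverse-strand gene placement (reverse-strand ORF handling is
exercised directly by the ORF-module tests). Passing the synthetic
acceptance checks therefore demonstrates the decision logic is correct
under its own assumptions, not that the thresholds are optimal for any
particular real dataset.

Default study size for acceptance checks is 200 genes (~225 transcripts),
which runs the full flow with the internal scorer in a few seconds;
rates and sizes are configurable without code changes.

## Numerical and degenerate-input choices

- E-values are computed in log space and underflow to exactly 0 below
  about 1e-304; the merge gate treats 0 ≤ 0 × factor as acceptance
  (both merged and parent evidence are beyond floating-point resolution).
- Best-hit ties break by higher bitscore, then first occurrence;
  dedup ties (identical sequences) keep the lexicographically smallest id;
  top-ORF ties prefer forward strand, then smaller start, then
  enumeration index. All outputs are deterministically ordered, so
  identical inputs give byte-identical files (manifest timestamp aside).
- An empty transcriptome, a transcript with no hits, or a comparison at a
  cutoff below every attainable E-value are all well-defined (empty
  outputs, exclusion, everything-missing respectively), not errors.
- Merges can only be gated when database sequences are available to
  re-score the merged candidate; with hit-table-only evidence the merge
  stage is skipped and the longer ORF represents each broken transcript.

## Known limitations

- "Same gene" is operationalised as *identical best-subject accession*.
  Against a multi-species database, fragments of one gene can hit
  homologous but distinct accessions and be misread as a chimera; a
  similarity-cluster notion of subject identity would relax this.
- The comparison module's repeat flag (fraction of the protein covered by
  duplicated exact 12-mers, threshold 0.5) is a triage aid only.
- At fragment sizes near the 40-residue floor the significance gate
  occasionally (correctly) refuses the weaker fragment, leaving a break
  unrepaired; this is the designed behaviour of evidence gating, not a
  recoverable error.
- No GFF/genome-coordinate gene models are produced: the output is a
  protein set with provenance, matching the evidence actually used.
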