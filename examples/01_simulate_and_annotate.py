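"""Generate a small synthetic study and run the full annotation flow.

Builds a 60-gene genome + transcriptome with planted assembler artifacts
(broken, chimeric, contaminant, redundant transcripts), annotates it, and
scores the result against the generator's ground truth.
"""

from transannot import run_pipeline
from transannot.simulate import SimConfig, evaluate_run, simulate

sim = simulate(SimConfig(n_genes=60, seed=7))
print(f"transcripts: {len(sim.transcriptome)}  scaffolds: {len(sim.genome)}  "
      f"database proteins: {len(sim.database)}")

result = run_pipeline(sim.transcriptome, genome=sim.genome, database=sim.database)

c = result.counts
print(f"excluded as extraneous: {c['excluded']}")
print(f"classified  UNIQUE={c['unique']}  MULTI_SAME={c['multi_same']}  "
      f"MULTI_DIFF={c['multi_diff']}  NO_MATCH={c['no_match']}")
print(f"linker merges accepted: {c['same_merges_accepted']}  "
      f"cross-transcript merges: {c['cross_merges_accepted']}  "
      f"chimera split records: {c['split_records']}")
print(f"final protein set: {c['final_records']} (after {c['dedup_removed']} dedup removals)")

scores = evaluate_run(result, sim.truth)
for key, val in scores.items():
    print(f"  {key}: {val:.3f}")
# Fractions are against ground truth: 1.0 means every planted contaminant
# was excluded, every chimera split, every break repaired, every clean
# gene recovered as exactly one record containing its true protein.
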