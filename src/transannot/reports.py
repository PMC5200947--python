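"""Writers for the pipeline's output files.

All coordinates written are 1-based inclusive; reverse-strand ORF spans
are displayed high-to-low. Files are plain text (FASTA / TSV / JSON) and
byte-stable for identical inputs, so reruns can be diffed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .compare import ComparisonReport
from .pipeline import PipelineResult, Thresholds
from .seqio import SequenceRecord, write_fasta

__all__ = [
    "write_annotation_fasta",
    "write_classification_tsv",
    "write_merge_log_tsv",
    "write_id_list",
    "write_comparison_tsv",
    "write_manifest",
]


def _fmt_e(e: float) -> str:
    if e == float("inf"):
        return "NA"
    return "0.0" if e == 0 else f"{e:.2e}"


def write_annotation_fasta(result: PipelineResult, path: str | Path) -> None:
    records = [
        SequenceRecord(
            rec.output_id,
            rec.aa_seq,
            f"provenance={rec.provenance} transcripts={','.join(rec.transcript_ids)} "
            f"subject={rec.subject_id or 'NA'} evalue={_fmt_e(rec.evalue)}",
            alphabet="aa",
        )
        for rec in result.records
    ]
    write_fasta(records, path)


def write_classification_tsv(result: PipelineResult, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("transcript_id\tcategory\tscaffold\tn_significant_orfs\tbest_subjects\n")
        for tid in sorted(result.classifications):
            cls = result.classifications[tid]
            out.write(
                "\t".join(
                    [
                        tid,
                        cls.category,
                        result.scaffold_map.get(tid, "-"),
                        str(len(cls.orf_best)),
                        ",".join(cls.subjects) or "-",
                    ]
                )
                + "\n"
            )


def write_merge_log_tsv(result: PipelineResult, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(
            "kind\tinput_1\tinput_2\tsubject\te1\te2\te_merged\taccepted\toverlap\tscaffold\n"
        )
        for d in result.merge_log:
            out.write(
                "\t".join(
                    [
                        d.kind,
                        d.input_ids[0],
                        d.input_ids[1],
                        d.subject_id,
                        _fmt_e(d.e1),
                        _fmt_e(d.e2),
                        _fmt_e(d.e_merged),
                        "yes" if d.accepted else "no",
                        d.overlap_aa or "-",
                        d.scaffold_id or "-",
                    ]
                )
                + "\n"
            )


def write_id_list(ids: List[str], path: str | Path) -> None:
    with open(path, "w") as out:
        for i in ids:
            out.write(i + "\n")


def write_comparison_tsv(report: ComparisonReport, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("set\tprotein_id\tstatus\tbest_partner\tevalue\trepeat_rich\n")
        for name, missing, matched in (
            (report.set_a_name, report.missing_in_b, report.matched_a),
            (report.set_b_name, report.missing_in_a, report.matched_b),
        ):
            for pid in missing:
                out.write(
                    f"{name}\t{pid}\tmissing\t-\tNA\t"
                    f"{'yes' if report.repeat_flags.get(pid) else 'no'}\n"
                )
            for pid in sorted(matched):
                partner, ev = matched[pid]
                out.write(
                    f"{name}\t{pid}\tmatched\t{partner}\t{_fmt_e(ev)}\t"
                    f"{'yes' if report.repeat_flags.get(pid) else 'no'}\n"
                )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    thresholds: Thresholds,
    inputs: Dict[str, Optional[str]],
    outputs: List[str],
    counts: Dict[str, int],
    seed: Optional[int] = None,
) -> None:
    """Run manifest: version, resolved thresholds, input digests, outputs
    and per-stage counts — enough to reproduce the run."""
    manifest = {
        "tool": "transannot",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "thresholds": asdict(thresholds),
        "inputs": {
            name: {"path": p, "sha256": _digest(Path(p))}
            for name, p in inputs.items()
            if p is not None
        },
        "outputs": outputs,
        "counts": counts,
    }
    with open(path, "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
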