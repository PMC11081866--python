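"""End-to-end orchestration: FASTQ -> alignments -> tables -> summaries.

Thin glue over the library modules, plus the read-accounting and
run-metadata bookkeeping: every processed sample records reads total /
merged / aligned / rejected by reason, and each output directory gets a
JSON sidecar with package version, parameters and seeds so a run can be
reproduced byte for byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .align import (AlignParams, Alignment, AlignmentRejected, MergeError,
                    global_align, merge_pairs)
from .quantify import (AlleleTable, EditingSummary, build_adenine_index,
                       build_allele_table, render_allele_table, summarize)
from .seqio import AmpliconSpec, SampleSheet, SequenceRead, parse_fastq


@dataclass
class ReadAccounting:
    """Where every input read (or pair) ended up."""

    total: int = 0
    merged: int = 0
    aligned: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1


def align_reads(
    reads: Iterable[SequenceRead],
    ref: str,
    params: AlignParams = AlignParams(),
    accounting: Optional[ReadAccounting] = None,
) -> list[Alignment]:
    """Align single-end reads, deduplicating identical sequences.

    Alignment depends only on the base string, so each distinct sequence
    is aligned once and the result reused (per-read ids are preserved).
    """
    acc = accounting if accounting is not None else ReadAccounting()
    cache: dict[str, Optional[Alignment]] = {}
    out = []
    for read in reads:
        acc.total += 1
        hit = cache.get(read.bases, "miss")
        if hit == "miss":
            try:
                hit = global_align(read, ref, params)
            except AlignmentRejected as exc:
                hit = None
                cache[read.bases] = None
                acc.reject(exc.reason)
                continue
            cache[read.bases] = hit
        elif hit is None:
            acc.reject("low_identity")
            continue
        acc.aligned += 1
        out.append(
            Alignment(
                read_id=read.id,
                aligned_read=hit.aligned_read,
                aligned_ref=hit.aligned_ref,
                score=hit.score,
                read_span=hit.read_span,
                strand=hit.strand,
                ops=hit.ops,
            )
        )
    return out


def process_sample(
    fastq1: str | Path,
    spec: AmpliconSpec,
    fastq2: Optional[str | Path] = None,
    params: AlignParams = AlignParams(),
) -> tuple[list[Alignment], ReadAccounting]:
    """Parse, optionally merge, and align one sample's reads."""
    acc = ReadAccounting()
    if fastq2 is None:
        alignments = align_reads(parse_fastq(fastq1), spec.reference, params, acc)
        acc.merged = acc.total
        return alignments, acc
    merged_reads = []
    for r1, r2 in zip(parse_fastq(fastq1), parse_fastq(fastq2), strict=True):
        try:
            merged_reads.append(merge_pairs(r1, r2, params.min_overlap))
        except MergeError as exc:
            acc.reject(exc.reason)
    acc.merged = len(merged_reads)
    inner = ReadAccounting()
    alignments = align_reads(merged_reads, spec.reference, params, inner)
    acc.total = acc.merged + sum(
        v for k, v in acc.rejected.items() if k == "no_overlap"
    )
    acc.aligned = inner.aligned
    for reason, count in inner.rejected.items():
        acc.rejected[reason] = acc.rejected.get(reason, 0) + count
    return alignments, acc


def summary_frame(summaries: Sequence[EditingSummary]) -> pd.DataFrame:
    """Flatten EditingSummary records into one tidy per-sample table."""
    rows = []
    for s in summaries:
        row = {
            "sample_id": s.sample_id,
            "n_aligned": s.n_aligned,
            "desired_only_rate": s.desired_only_rate,
            "synonymous_bystander_rate": s.synonymous_bystander_rate,
            "nonsynonymous_bystander_rate": s.nonsynonymous_bystander_rate,
            "indel_rate": s.indel_rate,
        }
        for label, rate in s.per_adenine_rate.items():
            row[f"rate_{label}"] = rate
        rows.append(row)
    return pd.DataFrame(rows)


def run_quant(
    sheet: SampleSheet,
    specs: Mapping[str, AmpliconSpec],
    out_dir: str | Path,
    params: AlignParams = AlignParams(),
    min_freq: float = 0.002,
    exclude_indels_from_denominator: bool = False,
) -> pd.DataFrame:
    """Quantify every sample in a sheet; write per-sample allele tables,
    a combined summary TSV and a run-metadata JSON.  Deterministic for
    fixed inputs.  Returns the summary table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = []
    accounting = {}
    for sample in sheet:
        spec = specs[sample.locus_name]
        try:
            alignments, acc = process_sample(
                sample.fastq1, spec, sample.fastq2, params
            )
            index = build_adenine_index(spec)
            table = build_allele_table(alignments, spec, sample.sample_id)
            summary = summarize(
                table, spec, index,
                exclude_indels_from_denominator=exclude_indels_from_denominator,
            )
        except Exception as exc:
            raise RuntimeError(
                f"sample {sample.sample_id} (locus {sample.locus_name}): {exc}"
            ) from exc
        summaries.append(summary)
        accounting[sample.sample_id] = {
            **asdict(acc),
            "window_excluded": table.n_window_excluded,
        }
        rendered = render_allele_table(table, spec, index, min_freq)
        rendered.to_csv(
            out_dir / f"{sample.sample_id}.alleles.tsv", sep="\t", index=False
        )
    frame = summary_frame(summaries)
    frame.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    write_run_metadata(
        out_dir / "run_metadata.json",
        stage="quant",
        params={
            **asdict(params),
            "min_freq": min_freq,
            "exclude_indels_from_denominator": exclude_indels_from_denominator,
        },
        accounting=accounting,
    )
    return frame


def write_run_metadata(path: str | Path, stage: str, **payload) -> None:
    meta = {
        "tool": "bequant",
        "version": __version__,
        "stage": stage,
        "python": platform.python_version(),
        **payload,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
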