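"""Editing-outcome quantification from accepted alignments.

Reads are digested to their gapped sequence over the quantification
window, grouped into an allele table, and summarised into the rates the
downstream analyses use: per-adenine A->G conversion, desired-edit-only
efficiency, synonymous/nonsynonymous bystander rates and the windowed
indel rate:

* desired-edit-only = reads whose sole deviation from reference within
  the quantification window is the target A->G and which carry no indel
  in the indel window, over all aligned reads;
* indel rate = reads with >= 1 inserted or deleted base whose
  left-aligned placement overlaps the indel window, over all aligned
  reads;
* per-adenine rate at A_x = reads carrying G (protospacer-strand sense)
  at that position, over aligned reads minus those whose deletion covers
  the position (N no-calls are excluded from numerator and denominator).

Reads with an indel in the indel window are counted once, as indel
reads, and do not enter the substitution classes.  Summary statistics
always use the unfiltered table; the report-level frequency cutoff
(default 0.20%) affects rendering only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import Alignment
from .consequence import annotate_allele
from .seqio import AmpliconSpec


class EmptyInputError(ValueError):
    """No accepted alignments for a sample."""


class UnsupportedConfigurationError(ValueError):
    """Locus geometry this quantifier does not support."""


# ---------------------------------------------------------------------------
# adenine index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdenineIndex:
    """A_x labels over the combined protospacer interval of a locus.

    Labels run A_1..A_k, 5'->3' on the protospacer strand, over every
    adenine in the union of the locus's protospacer intervals.
    """

    strand: str
    offsets: tuple[int, ...]   # reference offsets, in label order
    labels: tuple[str, ...]

    def label_of(self, offset: int) -> Optional[str]:
        try:
            return self.labels[self.offsets.index(offset)]
        except ValueError:
            return None

    def offset_of(self, label: str) -> int:
        return self.offsets[self.labels.index(label)]

    def items(self):
        return zip(self.labels, self.offsets)


def build_adenine_index(spec: AmpliconSpec) -> AdenineIndex:
    """Label the adenines of the combined protospacer interval.

    Raises :class:`UnsupportedConfigurationError` when a locus mixes
    protospacers from both strands; warns when the interval holds no
    adenine at all.
    """
    try:
        strand = spec.protospacer_strand
    except Exception as exc:
        raise UnsupportedConfigurationError(str(exc)) from exc
    positions = sorted({
        o for p in spec.protospacers for o in range(p.start, p.end)
    })
    adenine_base = "A" if strand == "+" else "T"
    offsets = [o for o in positions if spec.reference[o] == adenine_base]
    if strand == "-":
        offsets = offsets[::-1]  # 5'->3' on the protospacer strand
    if not offsets:
        warnings.warn(
            f"{spec.locus_name}: no adenine in the combined protospacer",
            stacklevel=2,
        )
    labels = tuple(f"A_{i + 1}" for i in range(len(offsets)))
    return AdenineIndex(strand=strand, offsets=tuple(offsets), labels=labels)


# ---------------------------------------------------------------------------
# per-read digest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadDigest:
    """What one aligned read says inside the analysis windows.

    ``window_seq`` is the gapped sequence over the quantification window:
    uppercase calls, ``-`` for deleted positions, lowercase for inserted
    bases (placed at their junction).  Indel intervals are recorded after
    left-alignment, deletions as half-open reference intervals and
    insertions as junction coordinates.
    """

    window_seq: str
    has_indel_in_window: bool
    deletions: tuple[tuple[int, int], ...]
    insertions: tuple[int, ...]


def _window_coverage(spec: AmpliconSpec) -> tuple[int, int]:
    return (
        min(spec.quant_window[0], spec.indel_window[0]),
        max(spec.quant_window[1], spec.indel_window[1]),
    )


def digest_alignment(aln: Alignment, spec: AmpliconSpec) -> Optional[ReadDigest]:
    """Digest one alignment; None when the read does not span the windows."""
    lo, hi = _window_coverage(spec)
    if aln.read_span[0] > lo or aln.read_span[1] < hi:
        return None
    ws, we = spec.quant_window
    is_, ie = spec.indel_window
    span0, span1 = aln.read_span

    window: list[str] = []
    deletions: list[tuple[int, int]] = []
    insertions: list[int] = []
    del_start: Optional[int] = None
    in_insert = False
    rp = 0
    for rc, gc in zip(aln.aligned_read, aln.aligned_ref):
        if gc == "-":  # insertion junction at reference coordinate rp
            if span0 < rp < span1:
                if not in_insert:
                    insertions.append(rp)
                    in_insert = True
                if ws < rp < we:
                    window.append(rc.lower())
            continue
        in_insert = False
        inside_span = span0 <= rp < span1
        if rc == "-" and inside_span:
            if del_start is None:
                del_start = rp
        else:
            if del_start is not None:
                deletions.append((del_start, rp))
                del_start = None
        if ws <= rp < we:
            window.append(rc if inside_span else "-")
        rp += 1
    if del_start is not None:
        deletions.append((del_start, rp))

    has_indel = any(a < ie and b > is_ for a, b in deletions) or any(
        is_ < p < ie for p in insertions
    )
    return ReadDigest(
        window_seq="".join(window),
        has_indel_in_window=has_indel,
        deletions=tuple(deletions),
        insertions=tuple(insertions),
    )


def _window_char(window_seq: str, spec: AmpliconSpec, offset: int) -> str:
    """Call at a reference offset inside the quant window ('-' = deleted)."""
    core = [c for c in window_seq if not c.islower()]
    return core[offset - spec.quant_window[0]]


def window_substitutions(window_seq: str, spec: AmpliconSpec) -> dict[int, str]:
    """Substitutions implied by a window string (N no-calls excluded)."""
    ws, we = spec.quant_window
    core = [c for c in window_seq if not c.islower()]
    subs = {}
    for k, c in enumerate(core):
        ref_base = spec.reference[ws + k]
        if c in "ACGT" and ref_base != "N" and c != ref_base:
            subs[ws + k] = c
    return subs


# ---------------------------------------------------------------------------
# allele table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleTable:
    """Aligned reads grouped by their window sequence and indel status."""

    rows: pd.DataFrame           # allele, count, frequency, substitutions, has_indel_in_window
    n_aligned: int
    n_window_excluded: int = 0
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.rows)


def build_allele_table(
    alignments: Sequence[Alignment],
    spec: AmpliconSpec,
    sample_id: str = "",
) -> AlleleTable:
    """Group accepted alignments into an allele table over the quant window.

    Frequencies are counts over the number of aligned reads spanning the
    analysis windows; reads not spanning them are dropped and counted in
    ``n_window_excluded``.  Raises :class:`EmptyInputError` when nothing
    remains.
    """
    counts: dict[tuple[str, bool], int] = {}
    excluded = 0
    for aln in alignments:
        digest = digest_alignment(aln, spec)
        if digest is None:
            excluded += 1
            continue
        key = (digest.window_seq, digest.has_indel_in_window)
        counts[key] = counts.get(key, 0) + 1
    n_aligned = sum(counts.values())
    if n_aligned == 0:
        raise EmptyInputError(
            f"sample {sample_id or '<unnamed>'}: no accepted alignments "
            "span the analysis windows"
        )
    records = []
    for (window_seq, has_indel), count in counts.items():
        subs = window_substitutions(window_seq, spec)
        records.append(
            {
                "allele": window_seq,
                "count": count,
                "frequency": count / n_aligned,
                "substitutions": tuple(sorted(subs.items())),
                "has_indel_in_window": has_indel,
            }
        )
    rows = pd.DataFrame.from_records(records).sort_values(
        ["count", "allele"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return AlleleTable(
        rows=rows,
        n_aligned=n_aligned,
        n_window_excluded=excluded,
        sample_id=sample_id,
    )


def filter_alleles_for_report(table: AlleleTable, min_freq: float = 0.002) -> AlleleTable:
    """Drop display rows below ``min_freq`` (default 0.20%).

    Frequencies keep their original denominator; use this only for
    rendering — every summary statistic runs on the unfiltered table.
    """
    kept = table.rows[table.rows["frequency"] >= min_freq].reset_index(drop=True)
    return AlleleTable(
        rows=kept,
        n_aligned=table.n_aligned,
        n_window_excluded=table.n_window_excluded,
        sample_id=table.sample_id,
    )


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def _desired_edit(spec: AmpliconSpec) -> tuple[int, str]:
    alt = "G" if spec.protospacer_strand == "+" else "C"
    return (spec.target_adenine, alt)


def _is_desired_only(row, spec: AmpliconSpec) -> bool:
    if row.has_indel_in_window:
        return False
    if "-" in row.allele or any(c.islower() for c in row.allele):
        return False
    return row.substitutions == (_desired_edit(spec),)


def desired_only_rate(table: AlleleTable, spec: AmpliconSpec) -> float:
    """Reads whose only in-window deviation is the target A->G, over all
    aligned reads."""
    num = sum(
        row.count for row in table.rows.itertuples()
        if _is_desired_only(row, spec)
    )
    return num / table.n_aligned


def per_adenine_rates(table: AlleleTable, index: AdenineIndex,
                      spec: AmpliconSpec) -> dict[str, float]:
    """Fraction of aligned reads carrying G at each A_x position.

    Reads whose deletion covers the position are excluded from both
    numerator and denominator, as are N no-calls at the position.
    """
    edited_base = "G" if index.strand == "+" else "C"
    ws, we = spec.quant_window
    rates = {}
    for label, offset in index.items():
        if not (ws <= offset < we):
            raise ValueError(
                f"{label} at offset {offset} lies outside the quant window"
            )
        num = 0
        denom = 0
        for row in table.rows.itertuples():
            c = _window_char(row.allele, spec, offset)
            if c in ("-", "N"):
                continue
            denom += row.count
            if c == edited_base:
                num += row.count
        rates[label] = num / denom if denom else 0.0
    return rates


def indel_rate(alignments: Sequence[Alignment], spec: AmpliconSpec) -> float:
    """Fraction of aligned reads with an indel overlapping the indel window."""
    n = 0
    hits = 0
    for aln in alignments:
        digest = digest_alignment(aln, spec)
        if digest is None:
            continue
        n += 1
        hits += digest.has_indel_in_window
    if n == 0:
        raise EmptyInputError("no alignments span the analysis windows")
    return hits / n


# ---------------------------------------------------------------------------
# per-sample summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditingSummary:
    """Per-sample editing outcome rates (all fractions of aligned reads)."""

    sample_id: str
    n_aligned: int
    desired_only_rate: float
    per_adenine_rate: Mapping[str, float]
    synonymous_bystander_rate: float
    nonsynonymous_bystander_rate: float
    indel_rate: float
    class_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        rates = [
            self.desired_only_rate,
            self.synonymous_bystander_rate,
            self.nonsynonymous_bystander_rate,
            self.indel_rate,
            *self.per_adenine_rate.values(),
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("rates must lie in [0, 1]")


def classify_rows(table: AlleleTable, spec: AmpliconSpec,
                  index: Optional[AdenineIndex] = None) -> pd.Series:
    """Outcome class per allele row (indel membership dominates)."""
    if index is None:
        index = build_adenine_index(spec)
    classes = []
    for row in table.rows.itertuples():
        if row.has_indel_in_window:
            classes.append("indel")
            continue
        _, cls = annotate_allele(dict(row.substitutions), spec, index.offsets)
        if cls == "on_target_only" and not _is_desired_only(row, spec):
            cls = "other"  # gap columns outside the indel window
        classes.append(cls)
    return pd.Series(classes, index=table.rows.index, name="class")


def summarize(
    table: AlleleTable,
    spec: AmpliconSpec,
    index: Optional[AdenineIndex] = None,
    exclude_indels_from_denominator: bool = False,
) -> EditingSummary:
    """EditingSummary for one sample from its unfiltered allele table.

    ``exclude_indels_from_denominator`` switches the substitution-class
    denominators from all aligned reads (default) to aligned reads minus
    indel reads; both behaviours are standard readings of "total aligned
    reads" and the choice is recorded in run metadata.
    """
    if index is None:
        index = build_adenine_index(spec)
    classes = classify_rows(table, spec, index)
    counts = table.rows["count"]
    class_counts: dict[str, int] = {}
    for cls, cnt in zip(classes, counts):
        class_counts[cls] = class_counts.get(cls, 0) + int(cnt)
    n = table.n_aligned
    n_indel = class_counts.get("indel", 0)
    denom = (n - n_indel) if exclude_indels_from_denominator else n
    denom = denom or 1
    return EditingSummary(
        sample_id=table.sample_id,
        n_aligned=n,
        desired_only_rate=class_counts.get("on_target_only", 0) / denom,
        per_adenine_rate=per_adenine_rates(table, index, spec),
        synonymous_bystander_rate=class_counts.get("synonymous_bystander", 0) / denom,
        nonsynonymous_bystander_rate=class_counts.get("nonsynonymous_bystander", 0) / denom,
        indel_rate=n_indel / n,
        class_counts=class_counts,
    )


def render_allele_table(
    table: AlleleTable,
    spec: AmpliconSpec,
    index: Optional[AdenineIndex] = None,
    min_freq: float = 0.002,
) -> pd.DataFrame:
    """Report-ready allele table with A_x substitution notation applied."""
    if index is None:
        index = build_adenine_index(spec)
    shown = filter_alleles_for_report(table, min_freq)
    classes = classify_rows(shown, spec, index)

    def notate(subs):
        parts = []
        for offset, alt in subs:
            label = index.label_of(offset)
            ref = spec.reference[offset]
            parts.append(
                f"{label}:{ref}>{alt}" if label else f"{offset}:{ref}>{alt}"
            )
        return ";".join(parts)

    out = shown.rows.copy()
    out["substitutions"] = [notate(s) for s in out["substitutions"]]
    out["class"] = classes.values
    return out
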