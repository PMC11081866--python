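"""Codon-level consequence calls for bystander substitutions.

Maps amplicon reference offsets to 1-based HGVS c. positions through the
locus's CDS anchor, substitutes the affected codon on the coding strand,
and classifies the change under the standard genetic code (translation
table 1).  Only the intra-amplicon coding segment is required; positions
outside it are reported ``noncoding``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq

from .seqio import AmpliconSpec, revcomp

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Allele classes in precedence order (an allele carrying both bystander
#: kinds counts once, as nonsynonymous).
ALLELE_CLASSES = (
    "nonsynonymous_bystander",
    "synonymous_bystander",
    "on_target_only",
    "other",
    "wildtype",
)


@dataclass(frozen=True)
class BystanderCall:
    """Consequence annotation for one substitution."""

    label: str                   # A_x label or 'offset<n>' for non-adenines
    ref_offset: int
    cds_position: Optional[int]  # 1-based c. coordinate; None if noncoding
    codon_number: Optional[int]
    position_in_codon: Optional[int]
    ref_codon: Optional[str]
    alt_codon: Optional[str]
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    consequence: str             # synonymous | nonsynonymous | stop_gained |
    #                              stop_lost | noncoding


def codon_index(cds_pos: int) -> tuple[int, int]:
    """(codon_number, position_in_codon), both 1-based, for a c. position."""
    if cds_pos < 1:
        raise ValueError(f"cds position {cds_pos} must be >= 1")
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3 + 1


def translate_codon(codon: str) -> str:
    """Single-letter amino acid ('*' for stop) under the standard code."""
    return str(Seq(codon).translate(table=1))


def _classify_codon(ref_codon: str, position_in_codon: int, alt: str) -> tuple[str, str, str, str]:
    """(alt_codon, ref_aa, alt_aa, consequence) for a codon substitution."""
    ref_codon = ref_codon.upper()
    alt = alt.upper()
    if len(ref_codon) != 3:
        raise ValueError(f"codon {ref_codon!r} is not a triplet")
    idx = position_in_codon - 1
    if ref_codon[idx] == alt:
        raise ValueError(
            f"alt base {alt} equals the reference at codon position "
            f"{position_in_codon} of {ref_codon}"
        )
    alt_codon = ref_codon[:idx] + alt + ref_codon[idx + 1:]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*":
        consequence = "stop_lost"
    else:
        consequence = "nonsynonymous"
    return alt_codon, ref_aa, alt_aa, consequence


def classify_substitution(cds_seq: str, cds_pos: int, alt: str) -> BystanderCall:
    """Classify a coding substitution given the CDS from c.1.

    ``cds_seq`` is coding-strand sequence whose first base is c.1 (or any
    in-frame prefix long enough to cover the affected codon); ``alt`` is
    the coding-strand alternate base.
    """
    if cds_pos < 1 or cds_pos > len(cds_seq):
        raise ValueError(f"cds position {cds_pos} outside the provided CDS")
    codon_number, pos_in_codon = codon_index(cds_pos)
    start = (codon_number - 1) * 3
    ref_codon = cds_seq[start:start + 3].upper()
    if len(ref_codon) < 3:
        raise ValueError(f"CDS segment does not cover codon {codon_number}")
    alt_codon, ref_aa, alt_aa, consequence = _classify_codon(
        ref_codon, pos_in_codon, alt
    )
    return BystanderCall(
        label=f"c.{cds_pos}",
        ref_offset=-1,
        cds_position=cds_pos,
        codon_number=codon_number,
        position_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )


def _cds_position(spec: AmpliconSpec, ref_offset: int) -> int:
    anchor_offset, anchor_c, strand = spec.cds_anchor
    if strand == "+":
        return anchor_c + (ref_offset - anchor_offset)
    return anchor_c + (anchor_offset - ref_offset)


def annotate_substitution(
    spec: AmpliconSpec, ref_offset: int, alt: str, label: str = ""
) -> BystanderCall:
    """Consequence call for one reference-strand substitution at a locus.

    The coding strand may differ from the reference strand; on '-' the
    substitution is complemented before the codon is rebuilt.  Positions
    outside ``cds_region`` (or loci without CDS annotation) come back
    ``noncoding`` with a warning.
    """
    label = label or f"offset{ref_offset}"
    noncoding = BystanderCall(
        label=label, ref_offset=ref_offset, cds_position=None,
        codon_number=None, position_in_codon=None, ref_codon=None,
        alt_codon=None, ref_aa=None, alt_aa=None, consequence="noncoding",
    )
    if spec.cds_anchor is None or spec.cds_region is None:
        return noncoding
    lo, hi = spec.cds_region
    if not (lo <= ref_offset < hi):
        warnings.warn(
            f"{spec.locus_name}: substitution at offset {ref_offset} falls "
            "outside the CDS segment; classified noncoding",
            stacklevel=2,
        )
        return noncoding
    strand = spec.cds_anchor[2]
    cds_pos = _cds_position(spec, ref_offset)
    codon_number, pos_in_codon = codon_index(cds_pos)
    # reference offsets of the codon bases, 5'->3' on the coding strand
    if strand == "+":
        codon_offsets = [ref_offset - (pos_in_codon - 1) + k for k in range(3)]
        coding_alt = alt.upper()
    else:
        codon_offsets = [ref_offset + (pos_in_codon - 1) - k for k in range(3)]
        coding_alt = _COMPLEMENT[alt.upper()]
    if any(not (lo <= o < hi) for o in codon_offsets):
        warnings.warn(
            f"{spec.locus_name}: codon for offset {ref_offset} is truncated "
            "by the CDS segment; classified noncoding",
            stacklevel=2,
        )
        return noncoding
    codon = "".join(
        spec.reference[o] if strand == "+" else _COMPLEMENT[spec.reference[o]]
        for o in codon_offsets
    )
    alt_codon, ref_aa, alt_aa, consequence = _classify_codon(
        codon, pos_in_codon, coding_alt
    )
    return BystanderCall(
        label=label,
        ref_offset=ref_offset,
        cds_position=cds_pos,
        codon_number=codon_number,
        position_in_codon=pos_in_codon,
        ref_codon=codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )


def annotate_allele(
    substitutions: Mapping[int, str],
    spec: AmpliconSpec,
    adenine_offsets: Optional[Iterable[int]] = None,
) -> tuple[list[BystanderCall], str]:
    """Annotate an allele's substitutions and assign its outcome class.

    ``substitutions`` maps reference offsets to reference-strand alternate
    bases.  Bystanders are A->G conversions (protospacer-strand sense) at
    non-target adenines; ``adenine_offsets`` restricts which offsets count
    as protospacer adenines (default: any offset that is A on the
    protospacer strand).  Class precedence: nonsynonymous_bystander >
    synonymous_bystander > on_target_only > other > wildtype.
    """
    proto_strand = spec.protospacer_strand
    desired_alt = "G" if proto_strand == "+" else "C"
    adenine_ref_base = "A" if proto_strand == "+" else "T"
    adenine_set = None if adenine_offsets is None else set(adenine_offsets)

    calls: list[BystanderCall] = []
    has_target = False
    has_nonsyn = False
    has_syn = False
    has_other = False
    for offset, alt in sorted(substitutions.items()):
        alt = alt.upper()
        is_adenine = (
            spec.reference[offset] == adenine_ref_base
            and (adenine_set is None or offset in adenine_set)
        )
        if offset == spec.target_adenine and alt == desired_alt:
            has_target = True
            continue
        if is_adenine and alt == desired_alt:
            call = annotate_substitution(spec, offset, alt)
            calls.append(call)
            if call.consequence in ("nonsynonymous", "stop_gained", "stop_lost"):
                has_nonsyn = True
            elif call.consequence == "synonymous":
                has_syn = True
            else:  # noncoding bystanders count with the synonymous class
                has_syn = True
        else:
            has_other = True

    if has_nonsyn:
        allele_class = "nonsynonymous_bystander"
    elif has_syn:
        allele_class = "synonymous_bystander"
    elif has_target and not has_other:
        allele_class = "on_target_only"
    elif has_target or has_other:
        allele_class = "other"
    else:
        allele_class = "wildtype"
    return calls, allele_class
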