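"""Sequence I/O and locus/sample configuration.

This module reads and writes the plain formats the pipeline touches —
FASTQ (Phred+33, optionally gzipped), FASTA references, a YAML locus
configuration and a TSV sample sheet — and validates the locus geometry
(protospacer placement, PAM, target adenine, analysis windows) eagerly,
so that every downstream stage can trust its coordinates.

All internal coordinates are 0-based, half-open intervals on the amplicon
reference.  1-based HGVS c. positions appear only in the ``consequence``
module.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO as BioSeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` position by position."""
    if len(pattern) != len(seq):
        return False
    for p, b in zip(pattern.upper(), seq.upper()):
        if p not in IUPAC:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern {pattern!r}")
        if b not in IUPAC[p]:
            return False
    return True


class FastqParseError(ValueError):
    """A FASTQ record could not be parsed; carries the 0-based record index."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"FASTQ record {index}: {message}")


class SpecValidationError(ValueError):
    """An AmpliconSpec or SampleSheet violated one of its invariants."""


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRead:
    """A single sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]
    mate: Optional[int] = None  # 1 or 2 for paired reads

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def to_fastq(self) -> str:
        qual = "".join(chr(q + 33) for q in self.quals)
        return f"@{self.id}\n{self.bases}\n+\n{qual}\n"


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream reads from a FASTQ file (Phred+33; gzip accepted by suffix).

    Yields reads in file order.  A malformed record (truncated entry,
    missing ``+`` separator, sequence/quality length mismatch) raises
    :class:`FastqParseError` naming the index of the offending record.
    """
    index = 0
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(index, str(exc)) from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    index, "sequence and quality lengths differ"
                )
            yield SequenceRead(
                id=title.split()[0] if title else f"read{index}",
                bases=seq.upper(),
                quals=tuple(ord(c) - 33 for c in qual),
            )
            index += 1


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write reads to ``path`` (gzipped if the suffix is .gz); returns count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(read.to_fastq())
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered {id: sequence} dict (uppercased)."""
    with _open_text(path) as handle:
        return {
            rec.id: str(rec.seq).upper()
            for rec in BioSeqIO.parse(handle, "fasta")
        }


# ---------------------------------------------------------------------------
# locus configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protospacer:
    """A guide protospacer placed on the amplicon reference."""

    sequence: str
    start: int      # 0-based offset of the 5'-most reference base it covers
    strand: str     # '+' or '-' relative to the reference
    pam: str        # IUPAC pattern, 3' of the protospacer on its strand
    label: str = ""

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class AmpliconSpec:
    """One targeted locus: amplicon reference plus editing geometry.

    ``nick_offset`` is the half-open junction coordinate of the nickase cut
    (canonically between protospacer positions 17 and 18, 3 bp 5' of the
    PAM).  ``quant_window`` bounds substitution calls; ``indel_window``
    covers both the deamination positions and the nick site.  ``cds_anchor``
    ties one reference base to its 1-based HGVS c. position on the stated
    coding strand; ``cds_region`` is the intra-amplicon coding segment used
    for consequence calls.
    """

    locus_name: str
    reference: str
    protospacers: tuple[Protospacer, ...]
    target_adenine: int
    nick_offset: int
    quant_window: tuple[int, int]
    indel_window: tuple[int, int]
    cds_anchor: Optional[tuple[int, int, str]] = None  # (ref offset, c. pos, strand)
    cds_region: Optional[tuple[int, int]] = None

    def __post_init__(self):
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        if not ref or set(ref) - set("ACGTN"):
            raise SpecValidationError(
                f"{self.locus_name}: reference must be a non-empty DNA string"
            )
        if not self.protospacers:
            raise SpecValidationError(f"{self.locus_name}: no protospacers")
        for proto in self.protospacers:
            self._check_protospacer(proto)
        for name, (lo, hi) in (
            ("quant_window", self.quant_window),
            ("indel_window", self.indel_window),
        ):
            if not (0 <= lo < hi <= len(ref)):
                raise SpecValidationError(
                    f"{self.locus_name}: {name} {lo, hi} outside reference bounds"
                )
        if not (self.quant_window[0] <= self.target_adenine < self.quant_window[1]):
            raise SpecValidationError(
                f"{self.locus_name}: target adenine {self.target_adenine} "
                f"outside quant_window {self.quant_window}"
            )
        if not (self.indel_window[0] <= self.nick_offset <= self.indel_window[1]):
            raise SpecValidationError(
                f"{self.locus_name}: indel_window must cover the nick site"
            )
        if not (self.indel_window[0] <= self.target_adenine < self.indel_window[1]):
            raise SpecValidationError(
                f"{self.locus_name}: indel_window must cover the deamination site"
            )
        # the pathogenic adenine must read A on the protospacer strand
        base = ref[self.target_adenine]
        expected = "A" if self.protospacer_strand == "+" else "T"
        if base != expected:
            raise SpecValidationError(
                f"{self.locus_name}: target offset {self.target_adenine} is "
                f"{base!r}, not an A on the protospacer strand"
            )
        if self.cds_region is not None:
            lo, hi = self.cds_region
            if not (0 <= lo < hi <= len(ref)):
                raise SpecValidationError(
                    f"{self.locus_name}: cds_region outside reference bounds"
                )
        if self.cds_anchor is not None and self.cds_anchor[2] not in "+-":
            raise SpecValidationError(
                f"{self.locus_name}: coding strand must be '+' or '-'"
            )

    def _check_protospacer(self, proto: Protospacer) -> None:
        ref = self.reference
        if proto.strand not in "+-":
            raise SpecValidationError(
                f"{self.locus_name}/{proto.label}: strand must be '+' or '-'"
            )
        if proto.start < 0 or proto.end > len(ref):
            raise SpecValidationError(
                f"{self.locus_name}/{proto.label}: protospacer outside reference"
            )
        slice_ = ref[proto.start:proto.end]
        expected = slice_ if proto.strand == "+" else revcomp(slice_)
        if proto.sequence.upper() != expected:
            raise SpecValidationError(
                f"{self.locus_name}/{proto.label}: protospacer does not match "
                f"the reference at offset {proto.start} on strand {proto.strand}"
            )
        # PAM is immediately 3' of the protospacer on its strand
        if proto.pam:
            plen = len(proto.pam)
            if proto.strand == "+":
                lo, hi = proto.end, proto.end + plen
                pam_seq = ref[lo:hi]
            else:
                lo, hi = proto.start - plen, proto.start
                pam_seq = revcomp(ref[lo:hi]) if lo >= 0 else ""
            if lo < 0 or hi > len(ref) or not iupac_match(proto.pam, pam_seq):
                raise SpecValidationError(
                    f"{self.locus_name}/{proto.label}: PAM {proto.pam} not "
                    f"found adjacent to the protospacer (saw {pam_seq!r})"
                )

    @property
    def protospacer_strand(self) -> str:
        strands = {p.strand for p in self.protospacers}
        if len(strands) > 1:
            raise SpecValidationError(
                f"{self.locus_name}: protospacers on both strands are not supported"
            )
        return strands.pop()

    @property
    def combined_protospacer_interval(self) -> tuple[int, int]:
        """Union interval of all protospacers (they overlap at one locus)."""
        return (
            min(p.start for p in self.protospacers),
            max(p.end for p in self.protospacers),
        )


def canonical_nick_offset(proto: Protospacer) -> int:
    """Junction coordinate of the SpCas9-nickase cut for one protospacer.

    The nick falls between protospacer positions 17 and 18 (1-based,
    5'->3' on the protospacer strand), i.e. 3 bp 5' of the PAM.
    """
    if proto.strand == "+":
        return proto.start + len(proto.sequence) - 3
    return proto.start + 3


def make_spec(
    locus_name: str,
    reference: str,
    protospacers: Sequence[Protospacer],
    target_adenine: int,
    cds_anchor: Optional[tuple[int, int, str]] = None,
    cds_region: Optional[tuple[int, int]] = None,
    nick_offset: Optional[int] = None,
    quant_window: Optional[tuple[int, int]] = None,
    indel_window: Optional[tuple[int, int]] = None,
    nick_pad: int = 3,
) -> AmpliconSpec:
    """Build a validated spec, deriving defaults from the guide geometry.

    Defaults: ``quant_window`` is the combined protospacer interval;
    ``nick_offset`` is the canonical cut of the first protospacer; the
    ``indel_window`` is the combined protospacer interval extended to
    cover ``[nick - nick_pad, nick + nick_pad)``.
    """
    protos = tuple(protospacers)
    if not protos:
        raise SpecValidationError(f"{locus_name}: no protospacers")
    lo = min(p.start for p in protos)
    hi = max(p.end for p in protos)
    if nick_offset is None:
        nick_offset = canonical_nick_offset(protos[0])
    if quant_window is None:
        quant_window = (lo, hi)
    if indel_window is None:
        indel_window = (
            min(lo, nick_offset - nick_pad),
            max(hi, nick_offset + nick_pad),
        )
    return AmpliconSpec(
        locus_name=locus_name,
        reference=reference,
        protospacers=protos,
        target_adenine=target_adenine,
        nick_offset=nick_offset,
        quant_window=quant_window,
        indel_window=indel_window,
        cds_anchor=cds_anchor,
        cds_region=cds_region,
    )


def load_amplicon_spec(path: str | Path) -> AmpliconSpec:
    """Load and validate a locus configuration from a YAML file.

    Keys: ``locus_name``, ``reference`` (inline DNA) or ``reference_fasta``
    (path, optionally ``reference_id``), ``protospacers`` (list of mappings
    with sequence/start/strand/pam/label), ``target_adenine``, and optional
    ``cds_anchor`` ({offset, c_pos, strand}), ``cds_region`` ([start, end]),
    ``nick_offset``, ``quant_window``, ``indel_window``.
    """
    path = Path(path)
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, Mapping):
        raise SpecValidationError(f"{path}: expected a YAML mapping")
    if "reference" in cfg:
        reference = cfg["reference"]
    elif "reference_fasta" in cfg:
        fasta = read_fasta(path.parent / cfg["reference_fasta"])
        ref_id = cfg.get("reference_id")
        if ref_id is None:
            reference = next(iter(fasta.values()))
        else:
            reference = fasta[ref_id]
    else:
        raise SpecValidationError(f"{path}: no reference or reference_fasta key")
    protos = [
        Protospacer(
            sequence=p["sequence"],
            start=int(p["start"]),
            strand=p["strand"],
            pam=p.get("pam", ""),
            label=p.get("label", f"sg{i + 1}"),
        )
        for i, p in enumerate(cfg.get("protospacers", []))
    ]
    anchor = cfg.get("cds_anchor")
    if anchor is not None:
        anchor = (int(anchor["offset"]), int(anchor["c_pos"]), anchor["strand"])
    region = cfg.get("cds_region")
    if region is not None:
        region = (int(region[0]), int(region[1]))

    def _window(key):
        win = cfg.get(key)
        return None if win is None else (int(win[0]), int(win[1]))

    return make_spec(
        locus_name=cfg.get("locus_name", path.stem),
        reference=reference,
        protospacers=protos,
        target_adenine=int(cfg["target_adenine"]),
        cds_anchor=anchor,
        cds_region=region,
        nick_offset=cfg.get("nick_offset"),
        quant_window=_window("quant_window"),
        indel_window=_window("indel_window"),
    )


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    fastq1: Path
    fastq2: Optional[Path]
    locus_name: str
    groups: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class SampleSheet:
    rows: tuple[SampleRow, ...]

    def __iter__(self) -> Iterator[SampleRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def load_sample_sheet(
    path: str | Path,
    known_loci: Optional[Iterable[str]] = None,
    check_files: bool = True,
) -> SampleSheet:
    """Load a TSV sample sheet (columns: sample_id, fastq1[, fastq2], locus,
    then free-form group columns such as treatment/genotype/sex/tissue).

    Relative FASTQ paths resolve against the sheet's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "fastq1", "locus"}
    missing = required - set(df.columns)
    if missing:
        raise SpecValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SpecValidationError(f"{path}: duplicated sample ids {dupes}")
    known = None if known_loci is None else set(known_loci)
    group_cols = [
        c for c in df.columns
        if c not in {"sample_id", "fastq1", "fastq2", "locus"}
    ]
    rows = []
    for rec in df.to_dict("records"):
        fq1 = path.parent / rec["fastq1"]
        fq2 = path.parent / rec["fastq2"] if rec.get("fastq2") else None
        if check_files:
            for fq in (fq1, fq2):
                if fq is not None and not fq.exists():
                    raise SpecValidationError(
                        f"{path}: sample {rec['sample_id']}: missing file {fq}"
                    )
        if known is not None and rec["locus"] not in known:
            raise SpecValidationError(
                f"{path}: sample {rec['sample_id']}: unknown locus {rec['locus']!r}"
            )
        rows.append(
            SampleRow(
                sample_id=rec["sample_id"],
                fastq1=fq1,
                fastq2=fq2,
                locus_name=rec["locus"],
                groups={c: rec[c] for c in group_cols},
            )
        )
    return SampleSheet(rows=tuple(rows))
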