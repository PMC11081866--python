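"""In-silico nomination of candidate off-target sites.

Scans both strands of a set of target sequences for positions within a
bounded Hamming distance of the protospacer whose adjacent PAM matches an
IUPAC pattern, merges nearby hits, and ranks the survivors by mismatch
count.  The default mismatch ceiling of 6 matches the threshold used for
targeted-amplicon verification of nominated sites; read-level pipeline
parameters of the wet discovery assay (mapq/start thresholds) have no
in-silico counterpart and are deliberately not modelled.

Editing at a nominated site is quantified by deriving an
:class:`~bequant.seqio.AmpliconSpec` from the site and running the
ordinary quantifier on reads from that amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .seqio import IUPAC, revcomp

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class OffTargetSearchParams:
    """Bounded-mismatch search parameters."""

    max_mismatches: int = 6
    pam_pattern: str = "NGN"
    allow_gaps: bool = False
    gap_threshold: int = 3
    window_size: int = 3     # merge hits within this many bp

    def __post_init__(self):
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        for c in self.pam_pattern.upper():
            if c not in IUPAC:
                raise ValueError(f"invalid IUPAC code {c!r} in PAM pattern")


@dataclass(frozen=True)
class OffTargetSite:
    """One candidate site on a target contig (protospacer-strand sequence)."""

    contig: str
    start: int          # 0-based on the contig's forward strand
    strand: str
    sequence: str
    mismatches: int
    pam: str
    pam_matches: bool
    rank: int = 0
    gapped: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def _pam_mask(contig_codes: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean mask: does the PAM pattern match starting at each offset?"""
    m = len(pattern)
    n = contig_codes.size
    ok = np.zeros(n, dtype=bool)
    if n < m:
        return ok
    valid = np.ones(n - m + 1, dtype=bool)
    for k, p in enumerate(pattern.upper()):
        allowed = np.array(
            ["ACGT"[c] in IUPAC[p] for c in range(4)] + [False], dtype=bool
        )
        valid &= allowed[contig_codes[k:n - m + 1 + k]]
    ok[: n - m + 1] = valid
    return ok


def _scan_strand(
    contig: str,
    seq: str,
    proto_codes: np.ndarray,
    params: OffTargetSearchParams,
    strand: str,
) -> list[OffTargetSite]:
    codes = _CODE[np.frombuffer(seq.encode(), np.uint8)]
    L = proto_codes.size
    plen = len(params.pam_pattern)
    n = codes.size
    if n < L + plen:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)[: n - L - plen + 1]
    # N (code 4) never equals an ACGT protospacer code, so it counts as a mismatch
    mism = (windows != proto_codes).sum(axis=1)
    pam_ok = _pam_mask(codes, params.pam_pattern)
    hits = []
    for pos in np.nonzero(mism <= params.max_mismatches)[0]:
        if not pam_ok[pos + L]:
            continue
        site_seq = seq[pos:pos + L]
        pam_seq = seq[pos + L:pos + L + plen]
        if strand == "+":
            start = int(pos)
        else:
            start = len(seq) - int(pos) - L
        hits.append(
            OffTargetSite(
                contig=contig,
                start=start,
                strand=strand,
                sequence=site_seq,
                mismatches=int(mism[pos]),
                pam=pam_seq,
                pam_matches=True,
            )
        )
    return hits


def _scan_gapped(
    contig: str,
    seq: str,
    protospacer: str,
    params: OffTargetSearchParams,
    strand: str,
) -> list[OffTargetSite]:
    """Bulged sites via bounded edit distance (edlib infix search)."""
    import edlib

    budget = params.max_mismatches + params.gap_threshold
    res = edlib.align(protospacer, seq, mode="HW", task="locations", k=budget)
    hits = []
    if res["editDistance"] < 0:
        return hits
    plen = len(params.pam_pattern)
    for lo, hi in res["locations"] or []:
        hi += 1  # edlib locations are inclusive
        gaps = abs((hi - lo) - len(protospacer))
        if gaps == 0 or gaps > params.gap_threshold:
            continue
        pam_seq = seq[hi:hi + plen]
        if len(pam_seq) < plen:
            continue
        from .seqio import iupac_match

        if not iupac_match(params.pam_pattern, pam_seq):
            continue
        start = lo if strand == "+" else len(seq) - hi
        hits.append(
            OffTargetSite(
                contig=contig,
                start=int(start),
                strand=strand,
                sequence=seq[lo:hi],
                mismatches=int(res["editDistance"]),
                pam=pam_seq,
                pam_matches=True,
                gapped=True,
            )
        )
    return hits


def find_candidate_sites(
    targets: Mapping[str, str],
    protospacer: str,
    params: OffTargetSearchParams = OffTargetSearchParams(),
) -> list[OffTargetSite]:
    """Enumerate and rank candidate sites across a set of sequences.

    Both strands are scanned; a hit requires Hamming distance to the
    protospacer <= ``max_mismatches`` and a PAM match immediately 3' of
    the site.  Hits whose starts lie within ``window_size`` bp on the
    same contig are merged keeping the lower-mismatch one.  Ranking is by
    (mismatch count, contig, start); ranks are 1-based.
    """
    if not targets:
        raise ValueError("empty target sequence set")
    protospacer = protospacer.upper()
    if len(protospacer) < 15:
        raise ValueError("protospacer must be at least 15 nt")
    proto_codes = _CODE[np.frombuffer(protospacer.encode(), np.uint8)]

    hits: list[OffTargetSite] = []
    for contig in sorted(targets):
        seq = targets[contig].upper()
        hits.extend(_scan_strand(contig, seq, proto_codes, params, "+"))
        hits.extend(_scan_strand(contig, revcomp(seq), proto_codes, params, "-"))
        if params.allow_gaps:
            hits.extend(_scan_gapped(contig, seq, protospacer, params, "+"))
            hits.extend(
                _scan_gapped(contig, revcomp(seq), protospacer, params, "-")
            )

    # merge nearby hits per contig, keeping the lower-mismatch one
    merged: list[OffTargetSite] = []
    for contig in sorted({h.contig for h in hits}):
        group = sorted(
            (h for h in hits if h.contig == contig),
            key=lambda h: (h.start, h.mismatches, h.strand),
        )
        cluster: list[OffTargetSite] = []
        for h in group:
            if cluster and h.start - cluster[-1].start <= params.window_size:
                cluster.append(h)
            else:
                if cluster:
                    merged.append(
                        min(cluster, key=lambda x: (x.mismatches, x.start, x.strand))
                    )
                cluster = [h]
        if cluster:
            merged.append(
                min(cluster, key=lambda x: (x.mismatches, x.start, x.strand))
            )

    merged.sort(key=lambda h: (h.mismatches, h.contig, h.start, h.strand))
    return [
        OffTargetSite(
            contig=h.contig, start=h.start, strand=h.strand,
            sequence=h.sequence, mismatches=h.mismatches, pam=h.pam,
            pam_matches=h.pam_matches, rank=i + 1, gapped=h.gapped,
        )
        for i, h in enumerate(merged)
    ]


def top_n_sites(sites: Sequence[OffTargetSite], n: int = 5) -> list[OffTargetSite]:
    """First ``n`` sites by rank (all of them when fewer exist)."""
    return sorted(sites, key=lambda h: h.rank)[:n]


def sites_to_bed(sites: Sequence[OffTargetSite]) -> str:
    """BED-like TSV: contig, start, end, strand, mismatches, sequence."""
    lines = ["#contig\tstart\tend\tstrand\tmismatches\tsequence\tpam\trank"]
    for s in sites:
        lines.append(
            f"{s.contig}\t{s.start}\t{s.end}\t{s.strand}\t{s.mismatches}"
            f"\t{s.sequence}\t{s.pam}\t{s.rank}"
        )
    return "\n".join(lines) + "\n"
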