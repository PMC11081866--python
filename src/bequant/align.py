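"""Read-pair merging and global alignment to the amplicon reference.

The aligner is an affine-gap Needleman-Wunsch/Gotoh with free end gaps on
the read side (a shorter read may start or end anywhere on the reference
without penalty, while the read itself must be fully explained).  A gap of
length k scores ``gap_open + k * gap_extend``.  N bases are scored 0
against anything so that no-calls neither support nor oppose an edit.

The dynamic program runs banded around the main diagonal (the band always
covers the read/reference length difference plus a pad); when the band
does not cover the whole matrix and the banded alignment fails the
identity threshold, the full matrix is recomputed before rejecting.  The
inner loops are numba-compiled.

Tie-breaking is deterministic: the traceback prefers diagonal moves, then
gap extension over gap opening, and a post-pass left-aligns every indel
run within homopolymers so that window membership never depends on
aligner internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .seqio import SequenceRead, revcomp

_CODE = np.full(256, 4, dtype=np.uint8)  # 4 = N / anything else
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_NEG = -1.0e18
_OP_DIAG, _OP_DEL, _OP_INS = 0, 1, 2

#: Maximum Phred score after summing agreeing overlap qualities.
MERGE_QUAL_CAP = 41


class AlignmentRejected(Exception):
    """Read could not be aligned acceptably; ``reason`` is a counted code."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


class MergeError(Exception):
    """Read pair could not be merged; ``reason`` is a counted code."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


@dataclass(frozen=True)
class AlignParams:
    """Scoring and acceptance parameters for the global aligner.

    Defaults make a 1-bp indel (−11) preferable to three scattered
    mismatches (−12 plus three lost matches), matching the intent of
    windowed indel calling.
    """

    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    min_identity: float = 0.6
    min_overlap: int = 10
    band_pad: int = 30

    def __post_init__(self):
        if not (self.match > 0 >= self.mismatch):
            raise ValueError("require mismatch <= 0 < match")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass(frozen=True)
class Alignment:
    """A gapped read-to-reference alignment.

    ``aligned_read`` and ``aligned_ref`` are equal-length strings covering
    the *entire* reference; columns outside ``read_span`` are free end
    gaps.  ``ops`` lists (op, length, ref_offset) runs with op in
    {'M','I','D'} ('M' covers matches and mismatches; insertions anchor at
    the reference junction before which they occur).
    """

    read_id: str
    aligned_read: str
    aligned_ref: str
    score: float
    read_span: tuple[int, int]     # half-open reference interval the read covers
    strand: str = "+"              # '-' if the read matched the reverse complement
    ops: tuple[tuple[str, int, int], ...] = ()

    @property
    def identity(self) -> float:
        matches = sum(
            1 for a, b in zip(self.aligned_read, self.aligned_ref)
            if a == b and a != "-"
        )
        read_len = sum(1 for a in self.aligned_read if a != "-")
        return matches / read_len if read_len else 0.0


@njit(cache=True)
def _gotoh_kernel(read, ref, match, mismatch, gap_open, gap_ext, lo, hi):
    """Banded affine DP with free read-side end gaps.

    Returns (score, ops, n_ops, start_col, end_col); ops are emitted in
    reverse (end to start) order with codes 0=diag, 1=del, 2=ins.
    """
    n = read.size
    m = ref.size
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in read (deletion of ref)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in ref (insertion)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = 0.0                  # free leading deletions
    for i in range(1, n + 1):
        Y[i, 0] = gap_open + i * gap_ext

    for i in range(1, n + 1):
        jlo = i + lo
        if jlo < 1:
            jlo = 1
        jhi = i + hi
        if jhi > m:
            jhi = m
        a = read[i - 1]
        for j in range(jlo, jhi + 1):
            b = ref[j - 1]
            if a >= 4 or b >= 4:
                s = 0.0
            elif a == b:
                s = match
            else:
                s = mismatch
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            if prev > _NEG / 2:
                M[i, j] = prev + s
            vx = M[i, j - 1] + gap_open + gap_ext
            t = X[i, j - 1] + gap_ext
            if t > vx:
                vx = t
            t = Y[i, j - 1] + gap_open + gap_ext
            if t > vx:
                vx = t
            if vx > _NEG / 2:
                X[i, j] = vx
            vy = M[i - 1, j] + gap_open + gap_ext
            t = Y[i - 1, j] + gap_ext
            if t > vy:
                vy = t
            t = X[i - 1, j] + gap_open + gap_ext
            if t > vy:
                vy = t
            if vy > _NEG / 2:
                Y[i, j] = vy

    # free trailing deletions: best cell anywhere on the last row
    best = _NEG
    bj = 0
    bstate = 0
    for j in range(0, m + 1):
        if M[n, j] > best:
            best = M[n, j]
            bj = j
            bstate = 0
        if Y[n, j] > best:
            best = Y[n, j]
            bj = j
            bstate = 2
        if X[n, j] > best:
            best = X[n, j]
            bj = j
            bstate = 1

    eps = 1e-9
    ops = np.empty(n + m + 2, dtype=np.int8)
    k = 0
    i = n
    j = bj
    state = bstate
    while i > 0:
        if state == 0:  # arrived by a diagonal move
            a = read[i - 1]
            b = ref[j - 1]
            if a >= 4 or b >= 4:
                s = 0.0
            elif a == b:
                s = match
            else:
                s = mismatch
            want = M[i, j] - s
            if abs(M[i - 1, j - 1] - want) < eps:
                state = 0
            elif abs(X[i - 1, j - 1] - want) < eps:
                state = 1
            else:
                state = 2
            ops[k] = _OP_DIAG
            k += 1
            i -= 1
            j -= 1
        elif state == 1:  # deletion column; prefer extending the gap
            v = X[i, j]
            if abs(X[i, j - 1] + gap_ext - v) < eps:
                state = 1
            elif abs(M[i, j - 1] + gap_open + gap_ext - v) < eps:
                state = 0
            else:
                state = 2
            ops[k] = _OP_DEL
            k += 1
            j -= 1
        else:  # insertion column; prefer extending the gap
            if j == 0:
                ops[k] = _OP_INS
                k += 1
                i -= 1
                continue
            v = Y[i, j]
            if abs(Y[i - 1, j] + gap_ext - v) < eps:
                state = 2
            elif abs(M[i - 1, j] + gap_open + gap_ext - v) < eps:
                state = 0
            else:
                state = 1
            ops[k] = _OP_INS
            k += 1
            i -= 1
    return best, ops, k, j, bj


def left_align_indels(aligned_read: str, aligned_ref: str) -> tuple[str, str]:
    """Shift every gap run as far left as the flanking sequence allows.

    A deletion run may move left one column whenever the reference base
    entering the run equals the one leaving it (homopolymer/repeat), and
    symmetrically for insertions; the alignment score is unchanged.
    """
    a = list(aligned_read)
    g = list(aligned_ref)
    n = len(a)
    changed = True
    while changed:
        changed = False
        c = 0
        while c < n:
            if a[c] == "-" and g[c] != "-":  # deletion run
                s = c
                e = c
                while e < n and a[e] == "-" and g[e] != "-":
                    e += 1
                while s > 0 and a[s - 1] != "-" and g[s - 1] != "-" \
                        and g[s - 1] == g[e - 1]:
                    a[e - 1] = a[s - 1]
                    a[s - 1] = "-"
                    s -= 1
                    e -= 1
                    changed = True
                c = max(e, c + 1)
            elif g[c] == "-":  # insertion run
                s = c
                e = c
                while e < n and g[e] == "-":
                    e += 1
                while s > 0 and g[s - 1] != "-" and a[s - 1] != "-" \
                        and a[s - 1] == a[e - 1]:
                    g[e - 1] = g[s - 1]
                    g[s - 1] = "-"
                    s -= 1
                    e -= 1
                    changed = True
                c = max(e, c + 1)
            else:
                c += 1
    return "".join(a), "".join(g)


def _ops_from_strings(aligned_read: str, aligned_ref: str) -> tuple[tuple[str, int, int], ...]:
    """Run-length (op, length, ref_offset) list from gapped strings."""
    ops = []
    ref_pos = 0
    for rc, gc in zip(aligned_read, aligned_ref):
        if gc == "-":
            op = "I"
            start = ref_pos
        elif rc == "-":
            op = "D"
            start = ref_pos
            ref_pos += 1
        else:
            op = "M"
            start = ref_pos
            ref_pos += 1
        if ops and ops[-1][0] == op and (op == "I" or ops[-1][1] + ops[-1][2] == start):
            ops[-1][2] += 1
        else:
            ops.append([op, start, 1])
    return tuple((op, length, start) for op, start, length in ops)


def _align_codes(read_codes, ref_codes, params: AlignParams, band: Optional[int]):
    m = ref_codes.size
    n = read_codes.size
    diff = m - n
    if band is None:
        lo, hi = -n, m  # full matrix
    else:
        lo = min(0, diff) - band
        hi = max(0, diff) + band
    return _gotoh_kernel(
        read_codes, ref_codes,
        params.match, params.mismatch, params.gap_open, params.gap_extend,
        lo, hi,
    )


def _build_alignment(read: SequenceRead, ref: str, strand: str,
                     bases: str, score, ops, k, j0, je) -> Alignment:
    parts_read = ["-" * j0]
    parts_ref = [ref[:j0]]
    i = 0
    j = j0
    for idx in range(k - 1, -1, -1):  # ops were emitted in reverse
        op = ops[idx]
        if op == _OP_DIAG:
            parts_read.append(bases[i])
            parts_ref.append(ref[j])
            i += 1
            j += 1
        elif op == _OP_DEL:
            parts_read.append("-")
            parts_ref.append(ref[j])
            j += 1
        else:
            parts_read.append(bases[i])
            parts_ref.append("-")
            i += 1
    parts_read.append("-" * (len(ref) - je))
    parts_ref.append(ref[je:])
    aligned_read = "".join(parts_read)
    aligned_ref = "".join(parts_ref)
    # normalise gap placement inside the aligned core only
    core_r, core_g = left_align_indels(
        aligned_read[j0:len(aligned_read) - (len(ref) - je)],
        aligned_ref[j0:len(aligned_ref) - (len(ref) - je)],
    )
    aligned_read = aligned_read[:j0] + core_r + aligned_read[len(aligned_read) - (len(ref) - je):]
    aligned_ref = aligned_ref[:j0] + core_g + aligned_ref[len(aligned_ref) - (len(ref) - je):]
    return Alignment(
        read_id=read.id,
        aligned_read=aligned_read,
        aligned_ref=aligned_ref,
        score=float(score),
        read_span=(j0, je),
        strand=strand,
        ops=tuple(
            (op, length, start + j0)
            for op, length, start in _ops_from_strings(core_r, core_g)
        ),
    )


def _align_oriented(read: SequenceRead, bases: str, ref: str,
                    params: AlignParams, strand: str) -> Alignment:
    read_codes = _CODE[np.frombuffer(bases.encode(), np.uint8)]
    ref_codes = _CODE[np.frombuffer(ref.encode(), np.uint8)]
    band = params.band_pad
    full = 2 * band + abs(ref_codes.size - read_codes.size) >= ref_codes.size
    score, ops, k, j0, je = _align_codes(
        read_codes, ref_codes, params, None if full else band
    )
    aln = _build_alignment(read, ref, strand, bases, score, ops, k, j0, je)
    if not full and aln.identity < params.min_identity:
        score, ops, k, j0, je = _align_codes(read_codes, ref_codes, params, None)
        aln = _build_alignment(read, ref, strand, bases, score, ops, k, j0, je)
    return aln


def global_align(read: SequenceRead, ref: str, params: AlignParams = AlignParams()) -> Alignment:
    """Optimal affine-gap global alignment of a read to the reference.

    End gaps on the read side are free.  If the forward orientation falls
    below ``min_identity`` the reverse complement is tried and, when it
    passes, returned with ``strand='-'`` (the aligned read shown reverse
    complemented).  Reads failing both orientations raise
    :class:`AlignmentRejected` with reason ``low_identity``.
    """
    if not read.bases or not ref:
        raise ValueError("read and reference must be non-empty")
    fwd = _align_oriented(read, read.bases, ref, params, "+")
    if fwd.identity >= params.min_identity:
        return fwd
    rev = _align_oriented(read, revcomp(read.bases), ref, params, "-")
    if rev.identity >= params.min_identity and rev.score > fwd.score:
        return rev
    raise AlignmentRejected(
        "low_identity",
        f"{read.id}: best identity "
        f"{max(fwd.identity, rev.identity):.3f} < {params.min_identity}",
    )


# ---------------------------------------------------------------------------
# read-pair merging
# ---------------------------------------------------------------------------

def merge_pairs(r1: SequenceRead, r2: SequenceRead, min_overlap: int = 10) -> SequenceRead:
    """Merge a forward read with its reverse-strand mate.

    The mate is reverse complemented and slid along r1; the best ungapped
    overlap is the offset maximising matches − mismatches (N-containing
    columns score 0), requiring an overlap of at least ``min_overlap``
    bases and a net score of at least ``min_overlap``.  Where the mates
    agree the merged quality is the capped sum of both Phreds; where they
    disagree the higher-quality base wins and keeps its own quality.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be positive")
    b2 = revcomp(r2.bases)
    q2 = tuple(reversed(r2.quals))
    n1, n2 = len(r1), len(b2)

    best_score = None
    best_off = None
    # offset = start of b2 relative to r1 (non-negative: amplicon layout)
    for off in range(0, n1 - min_overlap + 1):
        ov = min(n1 - off, n2)
        score = 0
        b1 = r1.bases
        for x in range(ov):
            a, b = b1[off + x], b2[x]
            if a == "N" or b == "N":
                continue
            score += 1 if a == b else -1
        if best_score is None or score > best_score:
            best_score = score
            best_off = off
    if best_score is None or best_score < min_overlap:
        raise MergeError(
            "no_overlap",
            f"{r1.id}: no ungapped overlap of >= {min_overlap} bases",
        )
    off = best_off
    ov = min(n1 - off, n2)
    bases = [*r1.bases[:off]]
    quals = [*r1.quals[:off]]
    for x in range(ov):
        a, qa = r1.bases[off + x], r1.quals[off + x]
        b, qb = b2[x], q2[x]
        if a == b:
            bases.append(a)
            quals.append(min(qa + qb, MERGE_QUAL_CAP))
        elif qa >= qb:
            bases.append(a)
            quals.append(qa)
        else:
            bases.append(b)
            quals.append(qb)
    bases.extend(b2[ov:])
    quals.extend(q2[ov:])
    return SequenceRead(id=r1.id, bases="".join(bases), quals=tuple(quals))
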