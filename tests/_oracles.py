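"""Independent oracles used by the test suite.

Everything here is deliberately written without reference to the package
implementation: a memoized-recursion affine-gap alignment scorer, a
literal standard genetic code table, a sliding-window Hamming off-target
scanner, and direct-summation statistics formulas.
"""

from __future__ import annotations

import math
from functools import lru_cache

# --------------------------------------------------------------------------
# affine-gap alignment score, free end gaps on the read side
# --------------------------------------------------------------------------

def affine_global_score(read: str, ref: str, match: float, mismatch: float,
                        gap_open: float, gap_extend: float) -> float:
    """Plain affine-gap global score; a gap of length k costs open + k*extend.

    N scores 0 against anything.  Memoized recursion over
    (i, j, previous-op); exponential state space kept tiny by len <= ~15.
    """

    @lru_cache(maxsize=None)
    def go(i: int, j: int, prev: int) -> float:
        if i == len(read) and j == len(ref):
            return 0.0
        best = -math.inf
        if i < len(read) and j < len(ref):
            if read[i] == "N" or ref[j] == "N":
                s = 0.0
            elif read[i] == ref[j]:
                s = match
            else:
                s = mismatch
            best = max(best, s + go(i + 1, j + 1, 0))
        if j < len(ref):  # gap in read (delete a reference base)
            cost = gap_extend + (gap_open if prev != 1 else 0.0)
            best = max(best, cost + go(i, j + 1, 1))
        if i < len(read):  # gap in reference (insert a read base)
            cost = gap_extend + (gap_open if prev != 2 else 0.0)
            best = max(best, cost + go(i + 1, j, 2))
        return best

    result = go(0, 0, 0)
    go.cache_clear()
    return result


def glocal_score(read: str, ref: str, match: float, mismatch: float,
                 gap_open: float, gap_extend: float) -> float:
    """Free-read-end-gap score = best plain global score over ref substrings."""
    best = -math.inf
    for j0 in range(len(ref) + 1):
        for je in range(j0, len(ref) + 1):
            best = max(
                best,
                affine_global_score(read, ref[j0:je], match, mismatch,
                                    gap_open, gap_extend),
            )
    return best


# --------------------------------------------------------------------------
# standard genetic code (translation table 1), as an explicit literal
# --------------------------------------------------------------------------

_CODON_LINES = """
TTT F  TTC F  TTA L  TTG L   TCT S  TCC S  TCA S  TCG S
TAT Y  TAC Y  TAA *  TAG *   TGT C  TGC C  TGA *  TGG W
CTT L  CTC L  CTA L  CTG L   CCT P  CCC P  CCA P  CCG P
CAT H  CAC H  CAA Q  CAG Q   CGT R  CGC R  CGA R  CGG R
ATT I  ATC I  ATA I  ATG M   ACT T  ACC T  ACA T  ACG T
AAT N  AAC N  AAA K  AAG K   AGT S  AGC S  AGA R  AGG R
GTT V  GTC V  GTA V  GTG V   GCT A  GCC A  GCA A  GCG A
GAT D  GAC D  GAA E  GAG E   GGT G  GGC G  GGA G  GGG G
"""

CODON_TABLE: dict[str, str] = {}
for _line in _CODON_LINES.strip().splitlines():
    _tokens = _line.split()
    for _codon, _aa in zip(_tokens[0::2], _tokens[1::2]):
        CODON_TABLE[_codon] = _aa
assert len(CODON_TABLE) == 64


# --------------------------------------------------------------------------
# off-target sliding-window Hamming scan
# --------------------------------------------------------------------------

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def _iupac_ok(pattern: str, seq: str) -> bool:
    table = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    return len(pattern) == len(seq) and all(
        b in table[p] for p, b in zip(pattern, seq)
    )


def hamming_site_scan(
    targets: dict[str, str], protospacer: str, pam: str, max_mismatches: int
) -> set[tuple[str, int, str, int]]:
    """All (contig, forward-strand start, strand, mismatches) site hits."""
    L = len(protospacer)
    hits = set()
    for contig, seq in targets.items():
        for strand in "+-":
            s = seq if strand == "+" else _revcomp(seq)
            for pos in range(len(s) - L - len(pam) + 1):
                window = s[pos:pos + L]
                mm = sum(1 for a, b in zip(window, protospacer) if a != b)
                if mm > max_mismatches:
                    continue
                if not _iupac_ok(pam, s[pos + L:pos + L + len(pam)]):
                    continue
                start = pos if strand == "+" else len(s) - pos - L
                hits.add((contig, start, strand, mm))
    return hits


# --------------------------------------------------------------------------
# direct-summation statistics
# --------------------------------------------------------------------------

def pearson_r_direct(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def welch_direct(a, b) -> tuple[float, float]:
    """(t, Satterthwaite df) from the textbook formulas."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def ddct_direct(ct_by_sample: dict[str, tuple[str, float, float]],
                sample_group: str, calibrator_group: str) -> float:
    """Spreadsheet-style ddCt: each value is (group, Ct_gene, Ct_ref)."""
    dct = {s: (g, cg - cr) for s, (g, cg, cr) in ct_by_sample.items()}
    mean = lambda grp: (
        sum(d for g, d in dct.values() if g == grp)
        / sum(1 for g, _ in dct.values() if g == grp)
    )
    return 2.0 ** (-(mean(sample_group) - mean(calibrator_group)))
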