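"""Synthetic demonstration locus.

The deposited sequencing data for the mouse Eif2b loci are not bundled
with this package, so examples and tests run on a fully synthetic locus
constructed here.  It emulates the geometry of an adenine-base-editing
target on a pathogenic transition variant: the amplicon carries a mutant
His codon (CAC) whose second-position adenine is the editing target
(A->G restores the Arg codon CGC), plus bystander adenines inside the
protospacer whose A->G conversions are nonsynonymous (GAT->GGT Asp->Gly,
GAC->GGC Asp->Gly) or synonymous (CGA->CGG, both Arg).

Everything returned by this module is synthetic; it is not the published
Eif2b4/Eif2b5 amplicon sequence.
"""

from __future__ import annotations

import numpy as np

from .seqio import AmpliconSpec, Protospacer, make_spec

#: Fixed codon block covering the protospacer and PAM (offsets 96..119).
_CORE = (
    "CTG"  # Leu          96-98
    "GAT"  # Asp (A_1)    99-101  second-position A->G is nonsynonymous
    "CAC"  # His (A_2)   102-104  target adenine at offset 103 (c.584)
    "CGA"  # Arg (A_3)   105-107  third-position A->G is synonymous
    "TTC"  # Phe         108-110
    "CTT"  # Leu         111-113
    "GAC"  # Asp (A_4)   114-116  second-position A->G is nonsynonymous
    "AGG"  # PAM (NGN)   117-119
)

_REF_LENGTH = 240
_CDS_REGION = (60, 180)         # in-frame coding segment within the amplicon
_CDS_ANCHOR = (60, 541, "+")    # offset 60 <-> c.541 on the + coding strand
_PROTO_START = 97               # protospacer covers offsets [97, 117)
TARGET_OFFSET = 103


def demo_reference(length: int = _REF_LENGTH) -> str:
    """Deterministic synthetic amplicon reference of the given length."""
    if length < 120:
        raise ValueError("demo reference must be at least 120 bp")
    rng = np.random.default_rng(20240307)
    bases = np.array(list("ACGT"))
    filler = rng.integers(0, 4, size=length)
    ref = list(bases[filler])
    ref[96:120] = list(_CORE)
    return "".join(ref)


def demo_locus() -> AmpliconSpec:
    """Synthetic single-guide locus with default windows and nick geometry.

    Protospacer: 20 nt on the + strand at offset 97 with an AGG (NGN) PAM;
    target adenine at offset 103 (protospacer position 7); nick between
    protospacer positions 17 and 18 (offset 114).  The combined-protospacer
    adenine index is A_1..A_4 at offsets 100, 103, 107, 115 with the target
    at A_2.
    """
    ref = demo_reference()
    proto = Protospacer(
        sequence=ref[_PROTO_START:_PROTO_START + 20],
        start=_PROTO_START,
        strand="+",
        pam="NGN",
        label="sg_demo",
    )
    return make_spec(
        locus_name="demo_locus",
        reference=ref,
        protospacers=[proto],
        target_adenine=TARGET_OFFSET,
        cds_anchor=_CDS_ANCHOR,
        cds_region=_CDS_REGION,
    )
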