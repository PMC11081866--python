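import pytest

from bequant import demo_locus, build_adenine_index
from bequant.align import AlignParams, global_align
from bequant.seqio import AmpliconSpec, Protospacer, SequenceRead, revcomp


@pytest.fixture(scope="session")
def spec() -> AmpliconSpec:
    return demo_locus()


@pytest.fixture(scope="session")
def index(spec):
    return build_adenine_index(spec)


@pytest.fixture(scope="session")
def mirrored_spec(spec) -> AmpliconSpec:
    """The demo locus on the opposite reference strand.

    The reference is reverse complemented and the protospacer/CDS
    annotations remapped, giving a '-'-strand locus that must behave
    identically to the forward one.
    """
    n = len(spec.reference)
    ref2 = revcomp(spec.reference)
    proto = spec.protospacers[0]
    proto2 = Protospacer(
        sequence=proto.sequence,
        start=n - proto.end,
        strand="-",
        pam=proto.pam,
        label=proto.label,
    )
    anchor_off, anchor_c, _ = spec.cds_anchor
    lo, hi = spec.cds_region
    return AmpliconSpec(
        locus_name="demo_locus_mirrored",
        reference=ref2,
        protospacers=(proto2,),
        target_adenine=n - 1 - spec.target_adenine,
        nick_offset=n - spec.nick_offset,
        quant_window=(n - spec.quant_window[1], n - spec.quant_window[0]),
        indel_window=(n - spec.indel_window[1], n - spec.indel_window[0]),
        cds_anchor=(n - 1 - anchor_off, anchor_c, "-"),
        cds_region=(n - hi, n - lo),
    )


@pytest.fixture(scope="session", autouse=True)
def _warm_aligner(spec):
    """Pay the JIT compilation cost once, before any timed test body."""
    read = SequenceRead("warm", spec.reference, (30,) * len(spec.reference))
    global_align(read, spec.reference, AlignParams())
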