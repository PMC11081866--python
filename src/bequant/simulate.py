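"""Synthetic amplicon read generation with known ground truth.

The simulator draws each read (or read pair) from a mixture of alleles —
reference, desired-edit-only, bystander-carrying and indel alleles — then
applies an independent per-base substitution error with a uniform choice
among the three non-reference bases.  A :class:`TruthManifest` captures
everything needed to regenerate the data bit-for-bit (one seed drives
allele assignment, error placement and error identity) and serves as the
ground-truth oracle for the quantifier.

The defaults of :func:`spiked_truth` mirror the in vivo study conditions
this package is built around: ~45.9% desired correction, ~4.8%
nonsynonymous bystander alleles and ~0.1% indels at the nick site, with
a 0.5% per-base sequencing error.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRead, revcomp, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class AlleleDef:
    """One haplotype over the amplicon: substitutions plus an optional indel.

    ``substitutions`` maps 0-based reference offsets to reference-strand
    alternate bases; ``indel`` is ``(position, length, 'ins'|'del')`` with
    the position a reference offset (insertions insert before it).
    """

    label: str
    substitutions: tuple[tuple[int, str], ...] = ()
    indel: Optional[tuple[int, int, str]] = None
    proportion: float = 0.0

    def apply(self, reference: str) -> str:
        """Reference sequence with this allele's edits applied."""
        seq = list(reference)
        for offset, alt in self.substitutions:
            if not (0 <= offset < len(reference)):
                raise ValueError(
                    f"allele {self.label}: substitution offset {offset} "
                    "outside the reference"
                )
            seq[offset] = alt
        out = "".join(seq)
        if self.indel is not None:
            pos, length, kind = self.indel
            if not (0 <= pos <= len(reference)) or length < 1:
                raise ValueError(
                    f"allele {self.label}: indel {self.indel} outside the reference"
                )
            if kind == "del":
                out = out[:pos] + out[pos + length:]
            elif kind == "ins":
                out = out[:pos] + "A" * length + out[pos:]
            else:
                raise ValueError(f"allele {self.label}: indel kind {kind!r}")
        return out


@dataclass(frozen=True)
class TruthManifest:
    """Ground truth for one simulated sample."""

    alleles: tuple[AlleleDef, ...]
    n_reads: int
    error_rate: float = 0.0
    qual: int = 37
    paired: bool = False
    read_length: Optional[int] = None  # None = full amplicon length
    seed: int = 0

    def __post_init__(self):
        total = sum(a.proportion for a in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele proportions sum to {total}, not 1")
        if any(a.proportion < 0 for a in self.alleles):
            raise ValueError("negative allele proportion")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["generator"] = "numpy.random.default_rng(PCG64)"
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        payload = json.loads(text)
        payload.pop("generator", None)
        alleles = tuple(
            AlleleDef(
                label=a["label"],
                substitutions=tuple(
                    (int(o), b) for o, b in a["substitutions"]
                ),
                indel=tuple(a["indel"]) if a["indel"] is not None else None,
                proportion=a["proportion"],
            )
            for a in payload.pop("alleles")
        )
        rl = payload.pop("read_length")
        return cls(
            alleles=alleles,
            read_length=None if rl is None else int(rl),
            **payload,
        )


@dataclass(frozen=True)
class SimulationResult:
    """Output paths plus the per-read allele labels the simulator drew."""

    fastq1: Path
    fastq2: Optional[Path]
    truth_path: Path
    labels: np.ndarray          # allele index per read (or pair)
    allele_labels: tuple[str, ...]

    def label_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=len(self.allele_labels))
        return dict(zip(self.allele_labels, counts.tolist()))


def _with_errors(codes: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Substitute each base with prob ``error_rate``, uniform over the others."""
    out = codes.copy()
    if error_rate > 0:
        mask = rng.random(codes.size) < error_rate
        k = int(mask.sum())
        if k:
            out[mask] = (out[mask] + rng.integers(1, 4, size=k)) % 4
    return out


def simulate_reads(
    spec,
    truth: TruthManifest,
    out_dir: str | Path,
    prefix: str = "sample",
) -> SimulationResult:
    """Write FASTQ file(s) for one sample and echo the manifest as JSON.

    Exactly ``truth.n_reads`` reads (or pairs) are produced; each is drawn
    from an allele by its proportion and then subjected to independent
    per-base errors.  Identical seeds give byte-identical files.  In paired
    mode the mates are perfectly overlapping full-length reads from
    opposite strands with independent error draws.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)

    allele_seqs = [a.apply(spec.reference) for a in truth.alleles]
    allele_codes = [_CODE[np.frombuffer(s.encode(), np.uint8)] for s in allele_seqs]
    if any((c == 255).any() for c in allele_codes):
        raise ValueError("allele sequences must be over {A,C,G,T}")
    props = np.array([a.proportion for a in truth.alleles], dtype=float)
    props = props / props.sum()  # exact renormalisation of float dust
    labels = rng.choice(len(truth.alleles), size=truth.n_reads, p=props)

    length = truth.read_length
    reads1: list[SequenceRead] = []
    reads2: list[SequenceRead] = []
    for i, idx in enumerate(labels):
        codes = allele_codes[idx]
        fwd = codes if length is None else codes[:length]
        r1 = _with_errors(fwd, truth.error_rate, rng)
        bases1 = _BASES[r1].tobytes().decode()
        quals = (truth.qual,) * len(bases1)
        reads1.append(SequenceRead(f"sim:{i}", bases1, quals, mate=1 if truth.paired else None))
        if truth.paired:
            rev = codes if length is None else codes[-length:]
            r2 = _with_errors(rev, truth.error_rate, rng)
            bases2 = revcomp(_BASES[r2].tobytes().decode())
            reads2.append(SequenceRead(f"sim:{i}", bases2, (truth.qual,) * len(bases2), mate=2))

    fq1 = out_dir / f"{prefix}_R1.fastq"
    write_fastq(reads1, fq1)
    fq2 = None
    if truth.paired:
        fq2 = out_dir / f"{prefix}_R2.fastq"
        write_fastq(reads2, fq2)
    truth_path = out_dir / f"{prefix}_truth.json"
    truth_path.write_text(truth.to_json())
    return SimulationResult(
        fastq1=fq1,
        fastq2=fq2,
        truth_path=truth_path,
        labels=labels,
        allele_labels=tuple(a.label for a in truth.alleles),
    )


def desired_alt_base(spec) -> str:
    """Reference-strand base written by the desired A->G edit."""
    return "G" if spec.protospacer_strand == "+" else "C"


def _nonsynonymous_bystander_offset(spec) -> int:
    """First non-target protospacer adenine whose A->G call is nonsynonymous.

    Falls back to the first non-target adenine when the locus carries no
    CDS annotation.
    """
    from .consequence import annotate_substitution
    from .quantify import build_adenine_index

    index = build_adenine_index(spec)
    alt = desired_alt_base(spec)
    candidates = [o for o in index.offsets if o != spec.target_adenine]
    if not candidates:
        raise ValueError(f"{spec.locus_name}: no bystander adenine available")
    if spec.cds_anchor is not None and spec.cds_region is not None:
        for offset in candidates:
            call = annotate_substitution(spec, offset, alt)
            if call.consequence in ("nonsynonymous", "stop_gained", "stop_lost"):
                return offset
    return candidates[0]


def spiked_truth(
    spec,
    on_target: float = 0.459,
    bystander: float = 0.048,
    indel: float = 0.001,
    error_rate: float = 0.005,
    n: int = 20_000,
    seed: int = 0,
    paired: bool = False,
) -> TruthManifest:
    """Study-condition allele mixture: desired edit, one nonsynonymous
    bystander allele (desired edit plus a second protospacer A->G), a 1-bp
    deletion at the nick site, and wildtype filling the remainder.
    """
    total = on_target + bystander + indel
    if total > 1.0 + 1e-12:
        raise ValueError(f"allele proportions sum to {total} > 1")
    alt = desired_alt_base(spec)
    target = (spec.target_adenine, alt)
    alleles = []
    if on_target > 0:
        alleles.append(AlleleDef("desired", (target,), None, on_target))
    if bystander > 0:
        bys_offset = _nonsynonymous_bystander_offset(spec)
        subs = tuple(sorted([target, (bys_offset, alt)]))
        alleles.append(AlleleDef("bystander", subs, None, bystander))
    if indel > 0:
        alleles.append(
            AlleleDef("indel", (), (spec.nick_offset, 1, "del"), indel)
        )
    alleles.append(AlleleDef("wildtype", (), None, 1.0 - total))
    return TruthManifest(
        alleles=tuple(alleles),
        n_reads=n,
        error_rate=error_rate,
        seed=seed,
        paired=paired,
    )


def expected_outcome_rates(spec, truth: TruthManifest) -> dict[str, float]:
    """Expected read-class fractions implied by a manifest.

    The quantifier classifies *reads*, and a read that catches a
    sequencing error inside the quantification window genuinely leaves
    the desired-edit-only class — so the ground truth for read-class
    fractions is the allele mixture pushed through the independent
    per-base error channel.  This closed form computes, per allele, the
    probability a read lands in each outcome class (positions are
    independent; an error at a position replaces its base uniformly by
    one of the other three), then mixes by allele proportion.  With
    ``error_rate == 0`` the result equals the allele proportions exactly.

    Alleles with an indel are attributed wholly to the indel class when
    the indel overlaps the indel window (substitution errors can neither
    create nor remove an indel under this simulator's error model).
    """
    import warnings

    from .consequence import annotate_substitution
    from .quantify import build_adenine_index

    e = truth.error_rate
    q = 1.0 - e
    ws, we = spec.quant_window
    is_, ie = spec.indel_window
    alt = desired_alt_base(spec)
    index = build_adenine_index(spec)
    nonsyn_offsets: list[int] = []
    syn_offsets: list[int] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for o in index.offsets:
            if o == spec.target_adenine:
                continue
            call = annotate_substitution(spec, o, alt)
            if call.consequence in ("nonsynonymous", "stop_gained", "stop_lost"):
                nonsyn_offsets.append(o)
            else:
                syn_offsets.append(o)

    out = {
        "desired_only": 0.0,
        "nonsynonymous_bystander": 0.0,
        "synonymous_bystander": 0.0,
        "indel": 0.0,
    }
    for allele in truth.alleles:
        if allele.indel is not None:
            pos, length, kind = allele.indel
            if kind == "del":
                in_window = pos < ie and pos + length > is_
            else:
                in_window = is_ < pos < ie
            if in_window:
                out["indel"] += allele.proportion
                continue
        subs = dict(allele.substitutions)

        def p_final(offset: int, required: str) -> float:
            start = subs.get(offset, spec.reference[offset])
            return q if start == required else e / 3.0

        p_desired = 1.0
        for o in range(ws, we):
            required = alt if o == spec.target_adenine else spec.reference[o]
            p_desired *= p_final(o, required)
        p_no_nonsyn = 1.0
        for o in nonsyn_offsets:
            p_no_nonsyn *= 1.0 - p_final(o, alt)
        p_no_syn = 1.0
        for o in syn_offsets:
            p_no_syn *= 1.0 - p_final(o, alt)
        out["desired_only"] += allele.proportion * p_desired
        out["nonsynonymous_bystander"] += allele.proportion * (1.0 - p_no_nonsyn)
        out["synonymous_bystander"] += allele.proportion * p_no_nonsyn * (1.0 - p_no_syn)
    return out


# ---------------------------------------------------------------------------
# downstream fixtures: phenotype cohort and qPCR plate
# ---------------------------------------------------------------------------

def simulate_cohort(
    n: int = 24,
    r_bodyweight: float = 0.54,
    r_grip: float = 0.06,
    r_traverse: float = 0.34,
    mean_bystander_pct: float = 4.8,
    sd_bystander_pct: float = 1.5,
    seed: int = 0,
    genotype: str = "het",
) -> pd.DataFrame:
    """Synthetic per-animal cohort with planted editing-phenotype correlations.

    Phenotype vectors are constructed by projecting noise orthogonally to
    the bystander-editing vector, so each planted Pearson r is exact in
    the sample (not just in expectation).  Requires n >= 3.
    """
    if n < 3:
        raise ValueError("cohort needs at least 3 animals")
    rng = np.random.default_rng(seed)
    x = rng.normal(mean_bystander_pct, sd_bystander_pct, size=n)
    zx = (x - x.mean()) / x.std()

    def planted(r: float, loc: float, scale: float) -> np.ndarray:
        e = rng.normal(size=n)
        e = e - e.mean() - (e @ zx / n) * zx  # orthogonal to zx, zero mean
        ze = e / e.std()
        return loc + scale * (r * zx + np.sqrt(1.0 - r * r) * ze)

    return pd.DataFrame(
        {
            "animal_id": [f"m{i + 1:03d}" for i in range(n)],
            "genotype": genotype,
            "sex": "f",
            "treatment": "ABEmax",
            "nonsyn_bystander_pct": x,
            "bodyweight_g": planted(r_bodyweight, 16.0, 1.5),
            "grip_strength_n": planted(r_grip, 1.0, 0.12),
            "traverse_time_s": np.maximum(
                planted(r_traverse, 20.0, 5.0), 0.5
            ),
        }
    )


def simulate_ct_table(
    genes: Sequence[str] = ("Gadd34", "Atf4", "Ddit3", "Trib3"),
    fold: float = 2.5,
    n_per_group: int = 4,
    noise_sd: float = 0.15,
    reference_gene: str = "Akt",
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic RT-qPCR Ct table with a planted fold upregulation.

    Two groups ('het' calibrator, 'hom') with per-sample technical noise on
    every Ct; the 'hom' group's target-gene Ct values are shifted by
    -log2(fold) so the delta-delta-Ct fold change recovers ``fold`` up to
    the noise.  Long format: sample, group, gene, ct.
    """
    rng = np.random.default_rng(seed)
    rows = []
    shift = float(np.log2(fold))
    for group in ("het", "hom"):
        for i in range(n_per_group):
            sample = f"{group}{i + 1}"
            rows.append((sample, group, reference_gene, 20.0 + rng.normal(0, noise_sd)))
            for gene in genes:
                ct = 24.0 + rng.normal(0, noise_sd)
                if group == "hom":
                    ct -= shift
                rows.append((sample, group, gene, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
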