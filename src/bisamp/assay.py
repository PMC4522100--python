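"""Target-panel model for two-round-PCR targeted bisulfite sequencing.

An assay panel is a small set of PCR amplicons designed against
bisulfite-converted genomic DNA. Round one (PCR#1) enriches each target
region with locus-specific primers carrying partial sequencing-adapter
overhangs; round two (PCR#2) extends those overhangs into full adapters
and adds a per-sample index barcode, so that products from many samples
can be pooled on a single run.

This module models the amplicons themselves: genomic intervals, region
sequences, CpG positions, primer footprints, in-silico bisulfite
conversion, primer assembly, and final library fragment-length
prediction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "PCR1_LEFT_OVERHANG",
    "PCR1_RIGHT_OVERHANG",
    "InvalidSequenceError",
    "GenomicInterval",
    "AdapterScheme",
    "TargetAssay",
    "BisulfiteTemplate",
    "AssayValidationReport",
    "reverse_complement",
    "bisulfite_convert",
    "enumerate_cpgs",
    "assemble_pcr1_primers",
    "predict_library_length",
    "validate_assay",
]

#: Partial Illumina adapter overhang prepended to every locus-specific
#: forward primer in the target-enrichment PCR (33 nt).
PCR1_LEFT_OVERHANG = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"

#: Partial adapter overhang prepended to every locus-specific reverse
#: primer in the target-enrichment PCR (34 nt).
PCR1_RIGHT_OVERHANG = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InvalidSequenceError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


def _check_sequence(seq: str) -> None:
    """Raise :class:`InvalidSequenceError` naming the first bad position."""
    for i, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise InvalidSequenceError(
                f"invalid nucleotide {base!r} at position {i}"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over {A, C, G, T, N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def bisulfite_convert(seq: str, protect_cpg: bool) -> str:
    """Convert a sequence as sodium bisulfite treatment would.

    Bisulfite deaminates unmethylated cytosine to uracil, which is
    amplified and sequenced as thymine; methylated cytosine (in mammals,
    essentially CpG-context cytosine) is protected and stays cytosine.

    Parameters
    ----------
    seq
        Nucleotide string over {A, C, G, T, N}.
    protect_cpg
        If True, model a fully methylated template: every C immediately
        followed by G is retained, all other Cs become T. If False,
        model a fully unmethylated template: every C becomes T.

    Returns
    -------
    str
        Converted sequence, same length as the input.
    """
    _check_sequence(seq)
    if not protect_cpg:
        return seq.replace("C", "T")
    out = list(seq)
    last = len(seq) - 1
    for i, base in enumerate(seq):
        if base == "C" and not (i < last and seq[i + 1] == "G"):
            out[i] = "T"
    return "".join(out)


def enumerate_cpgs(seq: str) -> list[int]:
    """Return ascending 0-based offsets o with ``seq[o:o+2] == "CG"``."""
    _check_sequence(seq)
    return [m.start() for m in re.finditer("CG", seq)]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval (as printed in assay tables).

    Internal pipeline arithmetic is all 0-based half-open; the
    ``from_bed``/``to_bed`` converters are the only place the shift
    happens.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_bed(cls, chrom: str, start0: int, end0: int, strand: str = "+") -> "GenomicInterval":
        """Build from BED-style 0-based half-open coordinates."""
        return cls(chrom, start0 + 1, end0, strand)

    def to_bed(self) -> tuple[str, int, int, str]:
        """Return BED-style (chrom, 0-based start, half-open end, strand)."""
        return (self.chrom, self.start - 1, self.end, self.strand)


@dataclass(frozen=True)
class AdapterScheme:
    """The constant sequence added around a target region by the two PCRs.

    PCR#1 prepends partial adapter overhangs to the locus-specific
    primers; PCR#2 primers anneal to those overhangs and extend them 5'
    into full flow-cell adapters, the right side carrying the sample
    index. With the defaults, a region of length L yields a final
    library fragment of L + 122 bp.

    Attributes
    ----------
    left_overhang, right_overhang
        PCR#1 partial adapter overhangs (33 and 34 nt by default).
    left_pcr2_extension_len
        Bases PCR#2 adds 5' of the left overhang (default 25).
    right_pcr2_tail_len
        Bases PCR#2 adds 5' of the right overhang beyond the index
        (default 24).
    index_len
        Sample barcode length (default 6).
    """

    left_overhang: str = PCR1_LEFT_OVERHANG
    right_overhang: str = PCR1_RIGHT_OVERHANG
    left_pcr2_extension_len: int = 25
    right_pcr2_tail_len: int = 24
    index_len: int = 6

    def __post_init__(self) -> None:
        _check_sequence(self.left_overhang)
        _check_sequence(self.right_overhang)
        for name in ("left_pcr2_extension_len", "right_pcr2_tail_len", "index_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def right_pcr2_extension_len(self) -> int:
        """Total bases added 5' of the right overhang in PCR#2 (tail + index)."""
        return self.right_pcr2_tail_len + self.index_len

    @property
    def added_length(self) -> int:
        """Total constant bases added around the region (122 by default)."""
        return (
            len(self.left_overhang)
            + len(self.right_overhang)
            + self.left_pcr2_extension_len
            + self.right_pcr2_extension_len
        )


@dataclass(frozen=True)
class TargetAssay:
    """One amplicon of a panel.

    ``region_seq`` is the primer-to-primer top-strand genomic sequence
    (unconverted reference space). Primers are stored in bisulfite
    space, i.e. as designed against the converted template: the forward
    primer matches the converted top strand, the reverse primer is the
    reverse complement of the converted top-strand 3' end.

    ``primer_footprints`` are 0-based half-open offset ranges of
    ``region_seq`` synthesized from primer oligos rather than template;
    bases there carry no methylation information.
    """

    name: str
    interval: GenomicInterval
    region_seq: str
    fwd_primer: str
    rev_primer: str
    cpg_offsets: tuple[int, ...] = ()
    primer_footprints: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        _check_sequence(self.region_seq)
        _check_sequence(self.fwd_primer)
        _check_sequence(self.rev_primer)
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("primers must be nonempty")
        if not self.cpg_offsets:
            object.__setattr__(
                self, "cpg_offsets", tuple(enumerate_cpgs(self.region_seq))
            )
        else:
            for o in self.cpg_offsets:
                if self.region_seq[o : o + 2] != "CG":
                    raise ValueError(
                        f"cpg_offset {o} is not a CpG in {self.name}: "
                        f"{self.region_seq[o:o+2]!r}"
                    )
        if not self.primer_footprints:
            n = len(self.region_seq)
            object.__setattr__(
                self,
                "primer_footprints",
                (
                    (0, len(self.fwd_primer)),
                    (n - len(self.rev_primer), n),
                ),
            )
        for lo, hi in self.primer_footprints:
            if not (0 <= lo <= hi <= len(self.region_seq)):
                raise ValueError(f"footprint ({lo}, {hi}) outside region bounds")

    @property
    def region_length(self) -> int:
        return len(self.region_seq)

    def in_footprint(self, offset: int) -> bool:
        """True if a region offset falls inside a primer footprint."""
        return any(lo <= offset < hi for lo, hi in self.primer_footprints)

    def non_cpg_c_offsets(self) -> list[int]:
        """Offsets of non-CpG cytosines outside primer footprints.

        These positions should read as T after complete conversion
        regardless of methylation; they estimate conversion efficiency.
        """
        cpg = set(self.cpg_offsets)
        return [
            i
            for i, b in enumerate(self.region_seq)
            if b == "C" and i not in cpg and not self.in_footprint(i)
        ]


@dataclass(frozen=True)
class BisulfiteTemplate:
    """In-silico bisulfite-converted strands of one assay's region.

    ``top_converted_unmeth`` has every C converted to T (fully
    unmethylated template); ``top_converted_meth`` retains CpG-context
    Cs (fully methylated). The bottom-strand counterparts are the same
    two conversions applied to the reverse complement of the region.
    """

    source: TargetAssay
    top_converted_unmeth: str
    top_converted_meth: str
    bottom_converted_unmeth: str
    bottom_converted_meth: str

    @classmethod
    def from_assay(cls, assay: TargetAssay) -> "BisulfiteTemplate":
        top = assay.region_seq
        bottom = reverse_complement(top)
        return cls(
            source=assay,
            top_converted_unmeth=bisulfite_convert(top, protect_cpg=False),
            top_converted_meth=bisulfite_convert(top, protect_cpg=True),
            bottom_converted_unmeth=bisulfite_convert(bottom, protect_cpg=False),
            bottom_converted_meth=bisulfite_convert(bottom, protect_cpg=True),
        )


def assemble_pcr1_primers(
    fwd: str, rev: str, scheme: AdapterScheme | None = None
) -> tuple[str, str]:
    """Prepend the PCR#1 partial-adapter overhangs to a primer pair.

    Returns ``(left_overhang + fwd, right_overhang + rev)``; lengths add
    exactly.
    """
    if scheme is None:
        scheme = AdapterScheme()
    if not fwd or not rev:
        raise ValueError("primers must be nonempty")
    _check_sequence(fwd)
    _check_sequence(rev)
    return scheme.left_overhang + fwd, scheme.right_overhang + rev


def predict_library_length(region_len: int, scheme: AdapterScheme | None = None) -> int:
    """Final sequencing-library fragment length for a region length.

    The final fragment is the target region plus both PCR#1 overhangs
    plus both PCR#2 extensions (including the sample index); with the
    default scheme this is ``region_len + 122``.
    """
    if scheme is None:
        scheme = AdapterScheme()
    if region_len <= 0:
        raise ValueError(f"region_len must be positive, got {region_len}")
    return region_len + scheme.added_length


@dataclass
class AssayValidationReport:
    """Design-rule check results for one assay (report-only, never fatal).

    ``cpgs_in_footprints`` lists CpG offsets whose methylation is
    unreadable because the bases come from primer oligos.
    ``primer_mismatches`` lists (primer, position, primer_base,
    template_base) where a primer base disagrees with the fully
    converted (unmethylated) template — e.g. a primer C over a template
    position that reads T after conversion.
    """

    assay_name: str
    cpgs_in_footprints: list[int] = field(default_factory=list)
    primer_mismatches: list[tuple[str, int, str, str]] = field(default_factory=list)
    library_length: int = 0

    @property
    def ok(self) -> bool:
        return not self.cpgs_in_footprints and not self.primer_mismatches


def validate_assay(
    assay: TargetAssay, scheme: AdapterScheme | None = None
) -> AssayValidationReport:
    """Check an assay's design rules.

    Flags (a) CpGs inside primer footprints, (b) primer bases
    inconsistent with the unmethylated bisulfite-converted template
    (compared character-wise), and (c) reports the predicted final
    library length.
    """
    if scheme is None:
        scheme = AdapterScheme()
    report = AssayValidationReport(assay_name=assay.name)
    report.cpgs_in_footprints = [
        o for o in assay.cpg_offsets if assay.in_footprint(o)
    ]
    converted = bisulfite_convert(assay.region_seq, protect_cpg=False)
    # Forward primer reads the converted top strand left to right.
    for i, base in enumerate(assay.fwd_primer):
        if i < len(converted) and base != converted[i]:
            report.primer_mismatches.append(("fwd", i, base, converted[i]))
    # Reverse primer is the reverse complement of the converted 3' end.
    expected_rev = reverse_complement(converted[-len(assay.rev_primer):])
    for i, base in enumerate(assay.rev_primer):
        if base != expected_rev[i]:
            report.primer_mismatches.append(("rev", i, base, expected_rev[i]))
    report.library_length = predict_library_length(assay.region_length, scheme)
    return report
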