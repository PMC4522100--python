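"""Reduced-alphabet read assignment and amplicon-anchored alignment.

Bisulfite conversion makes the read base at a cytosine position depend
on its methylation state (C if methylated, T if not). Aligning in a
reduced three-letter alphabet — every C collapsed to T on both read and
reference — removes that dependence, so methylation never counts as a
mismatch. After placement, the ORIGINAL read base at each reference
position is recovered; those bases carry the methylation signal.

Amplicon reads have fixed structure (they all start at a primer), so
alignment reduces to an exhaustive ungapped sliding-offset scan over a
short reference: exact, and trivially verifiable against brute force.
R2 (the second mate) is reverse-complemented before alignment so both
mates are placed on the top (left-primer) strand of the amplicon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .assay import TargetAssay, reverse_complement

__all__ = [
    "AlignmentConfig",
    "AmpliconAlignment",
    "AssignmentResult",
    "reduce_alphabet",
    "assign_read_pair",
    "align_to_amplicon",
    "mask_primer_positions",
    "encode_seq",
    "decode_seq",
    "batch_min_mismatch_offsets",
]

_REDUCE = str.maketrans("C", "T")
_REDUCE_U8 = np.arange(256, dtype=np.uint8)
_REDUCE_U8[ord("C")] = ord("T")


def reduce_alphabet(seq: str) -> str:
    """Collapse C to T (three-letter bisulfite matching alphabet)."""
    return seq.translate(_REDUCE)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 byte array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass(frozen=True)
class AlignmentConfig:
    """Thresholds for assignment and alignment.

    ``max_mismatch_frac`` caps accepted reduced-alphabet mismatches at a
    fraction of the aligned length. ``assignment_margin`` is how many
    mismatches worse the runner-up amplicon must be for an assignment to
    be trusted; ties and near-ties go to the unassigned bin.
    """

    max_mismatch_frac: float = 0.10
    assignment_margin: int = 5

    def mismatch_ceiling(self, aligned_len: int) -> int:
        return math.floor(self.max_mismatch_frac * aligned_len)


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of assigning one read pair to an amplicon.

    ``assay_name`` is None when unassigned; ``reason`` is then one of
    ``"ceiling"`` (best candidate too distant) or ``"tie"`` (runner-up
    within the margin).
    """

    assay_name: str | None
    mismatches: dict[str, int]
    reason: str | None = None

    @property
    def assigned(self) -> bool:
        return self.assay_name is not None


@dataclass(frozen=True)
class AmpliconAlignment:
    """Placement of one mate on the top strand of one amplicon.

    ``observed`` holds the read's original (unreduced) bases in
    reference orientation, covering reference offsets
    ``[offset, offset + len(observed))``. ``masked`` is the set of
    reference offsets flagged unusable for methylation calling (primer
    footprints).
    """

    assay_name: str
    mate: str  # "R1" or "R2"
    offset: int
    n_mismatch: int
    observed: str
    masked: frozenset[int] = field(default_factory=frozenset)

    @property
    def end(self) -> int:
        return self.offset + len(self.observed)

    def covers(self, ref_offset: int) -> bool:
        return self.offset <= ref_offset < self.end

    def base_at(self, ref_offset: int) -> str:
        """Observed original base at a covered reference offset."""
        return self.observed[ref_offset - self.offset]


def _count_mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _pair_panel_mismatches(
    r1: str, r2: str, assay: TargetAssay
) -> int:
    """Total reduced-alphabet mismatches of a pair against one amplicon.

    R1 is compared against the region prefix, the reverse complement of
    R2 against the region suffix (both reduced).
    """
    ref = reduce_alphabet(assay.region_seq)
    red1 = reduce_alphabet(r1)
    l1 = min(len(red1), len(ref))
    mm = _count_mismatches(red1[:l1], ref[:l1])
    red2 = reduce_alphabet(reverse_complement(r2))
    l2 = min(len(red2), len(ref))
    mm += _count_mismatches(red2[-l2:], ref[-l2:])
    return mm


def assign_read_pair(
    r1: str,
    r2: str,
    panel: Sequence[TargetAssay],
    config: AlignmentConfig | None = None,
) -> AssignmentResult:
    """Assign a read pair to the amplicon it most plausibly derives from.

    The amplicon with the fewest total reduced-alphabet mismatches wins
    if it meets the mismatch ceiling AND beats the runner-up by the
    configured margin; otherwise the pair is unassigned (a value, not an
    error).
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    if config is None:
        config = AlignmentConfig()
    mismatches = {a.name: _pair_panel_mismatches(r1, r2, a) for a in panel}
    ranked = sorted(mismatches.items(), key=lambda kv: kv[1])
    best_name, best_mm = ranked[0]
    best_assay = next(a for a in panel if a.name == best_name)
    aligned_len = min(len(r1), best_assay.region_length) + min(
        len(r2), best_assay.region_length
    )
    if best_mm > config.mismatch_ceiling(aligned_len):
        return AssignmentResult(None, mismatches, reason="ceiling")
    if len(ranked) > 1 and ranked[1][1] - best_mm < config.assignment_margin:
        return AssignmentResult(None, mismatches, reason="tie")
    return AssignmentResult(best_name, mismatches)


def align_to_amplicon(
    read: str,
    assay: TargetAssay,
    mate: str = "R1",
    config: AlignmentConfig | None = None,
) -> AmpliconAlignment | None:
    """Place one mate on an amplicon by exhaustive min-mismatch scan.

    The read (reverse-complemented first if ``mate == "R2"``) is slid
    ungapped over the reduced-alphabet reference; the offset with the
    fewest reduced-alphabet mismatches wins, ties broken toward the
    smallest offset. Returns None when the best placement still exceeds
    the mismatch ceiling (the record is discarded; callers count the
    rejection).
    """
    if config is None:
        config = AlignmentConfig()
    if mate not in ("R1", "R2"):
        raise ValueError(f"mate must be 'R1' or 'R2', got {mate!r}")
    oriented = reverse_complement(read) if mate == "R2" else read
    ref = reduce_alphabet(assay.region_seq)
    red = reduce_alphabet(oriented)
    l = len(red)
    if l > len(ref):
        # Read overruns the amplicon (e.g. read-through into adapter);
        # anchor by truncation to reference length.
        oriented = oriented[: len(ref)] if mate == "R1" else oriented[-len(ref):]
        red = reduce_alphabet(oriented)
        l = len(red)
    best_offset, best_mm = 0, l + 1
    for offset in range(len(ref) - l + 1):
        mm = _count_mismatches(red, ref[offset : offset + l])
        if mm < best_mm:
            best_offset, best_mm = offset, mm
    if best_mm > config.mismatch_ceiling(l):
        return None
    return AmpliconAlignment(
        assay_name=assay.name,
        mate=mate,
        offset=best_offset,
        n_mismatch=best_mm,
        observed=oriented,
    )


def mask_primer_positions(
    alignment: AmpliconAlignment, assay: TargetAssay
) -> AmpliconAlignment:
    """Flag covered reference positions inside primer footprints.

    Bases there were synthesized from primer oligos, not template, so
    they are unusable for methylation calling. Half-open footprints:
    a position at a footprint's ``end`` is NOT masked.
    """
    masked = {
        pos
        for lo, hi in assay.primer_footprints
        for pos in range(max(lo, alignment.offset), min(hi, alignment.end))
    }
    if not masked:
        return alignment
    return replace(alignment, masked=frozenset(alignment.masked | masked))


# ---------------------------------------------------------------------------
# Vectorized batch path (identical contract to align_to_amplicon; used by
# the pipeline so that studies with hundreds of thousands of pairs run in
# seconds). Equality with the scalar path is asserted in the test suite.
# ---------------------------------------------------------------------------


def batch_min_mismatch_offsets(
    reads: np.ndarray, ref_reduced: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive min-mismatch placement for a block of equal-length reads.

    Parameters
    ----------
    reads
        (n_reads, read_len) uint8 array of REDUCED-alphabet, reference-
        oriented read bytes.
    ref_reduced
        (ref_len,) uint8 array of the reduced reference.

    Returns
    -------
    offsets, mismatches
        Per-read best offset (smallest on ties) and its mismatch count.
    """
    n, l = reads.shape
    n_offsets = len(ref_reduced) - l + 1
    if n_offsets < 1:
        raise ValueError("reads longer than reference")
    best_mm = np.full(n, l + 1, dtype=np.int32)
    best_off = np.zeros(n, dtype=np.int32)
    for offset in range(n_offsets):
        mm = (reads != ref_reduced[offset : offset + l]).sum(axis=1, dtype=np.int32)
        better = mm < best_mm
        best_mm[better] = mm[better]
        best_off[better] = offset
    return best_off, best_mm


def batch_assign_pairs(
    r1: np.ndarray,
    r2_oriented: np.ndarray,
    panel: Sequence[TargetAssay],
    config: AlignmentConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pair-to-amplicon assignment for equal-length mates.

    ``r1`` and ``r2_oriented`` are (n, read_len) uint8 arrays in the
    REDUCED alphabet, R2 already reverse-complemented into reference
    orientation. Returns (assay_index, reason) where assay_index is -1
    for unassigned and reason is 0 assigned / 1 ceiling / 2 tie.
    """
    if config is None:
        config = AlignmentConfig()
    n = r1.shape[0]
    totals = np.empty((len(panel), n), dtype=np.int32)
    aligned_lens = np.empty(len(panel), dtype=np.int32)
    for k, assay in enumerate(panel):
        ref = encode_seq(reduce_alphabet(assay.region_seq))
        l1 = min(r1.shape[1], len(ref))
        l2 = min(r2_oriented.shape[1], len(ref))
        mm1 = (r1[:, :l1] != ref[:l1]).sum(axis=1, dtype=np.int32)
        mm2 = (r2_oriented[:, -l2:] != ref[-l2:]).sum(axis=1, dtype=np.int32)
        totals[k] = mm1 + mm2
        aligned_lens[k] = l1 + l2
    order = np.argsort(totals, axis=0, kind="stable")
    best_idx = order[0]
    best_mm = totals[best_idx, np.arange(n)]
    ceilings = np.floor(config.max_mismatch_frac * aligned_lens).astype(np.int32)
    over_ceiling = best_mm > ceilings[best_idx]
    reason = np.zeros(n, dtype=np.int8)
    reason[over_ceiling] = 1
    if len(panel) > 1:
        runner_mm = totals[order[1], np.arange(n)]
        tied = (runner_mm - best_mm < config.assignment_margin) & ~over_ceiling
        reason[tied] = 2
    assay_index = np.where(reason == 0, best_idx, -1).astype(np.int32)
    return assay_index, reason
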