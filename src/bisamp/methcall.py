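"""Per-CpG methylation calling from amplicon alignments.

At each CpG the observed original read base is the methylation signal:
C means the cytosine was protected (methylated), T means it was
converted (unmethylated), anything else is ambiguous and excluded from
the denominator. When the two mates of a pair overlap, any CpG covered
by the first read is ignored in the second read, so no molecule
contributes more than one call per CpG. The methylation fraction at a
CpG is the merged frequency of cytosines divided by total informative
calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .align import AmpliconAlignment
from .assay import TargetAssay

__all__ = [
    "METHYLATED",
    "UNMETHYLATED",
    "AMBIGUOUS",
    "CpGCall",
    "call_read_cpgs",
    "merge_pair_calls",
    "fraction_methylated",
    "MethylationAccumulator",
    "conversion_efficiency",
    "conversion_efficiency_from_counts",
    "coverage_filter",
    "MATRIX_COLUMNS",
]

METHYLATED = "M"
UNMETHYLATED = "U"
AMBIGUOUS = "X"

#: Column layout of the long-format methylation matrix.
MATRIX_COLUMNS = [
    "sample",
    "assay",
    "cpg_offset",
    "count_c",
    "count_t",
    "count_ambiguous",
    "fraction",
]


class CpGCall(NamedTuple):
    """One methylation call: state of one CpG on one read."""

    assay: str
    cpg_offset: int
    state: str  # METHYLATED / UNMETHYLATED / AMBIGUOUS


def _state_of(base: str) -> str:
    if base == "C":
        return METHYLATED
    if base == "T":
        return UNMETHYLATED
    return AMBIGUOUS


def call_read_cpgs(
    alignment: AmpliconAlignment, assay: TargetAssay
) -> list[CpGCall]:
    """Call every covered, unmasked CpG of one aligned mate.

    Observed C maps to methylated, T to unmethylated, anything else
    (sequencing error, N) to ambiguous; positions masked as primer
    footprint are omitted entirely.
    """
    calls = []
    for o in assay.cpg_offsets:
        if not alignment.covers(o) or o in alignment.masked:
            continue
        calls.append(CpGCall(assay.name, o, _state_of(alignment.base_at(o))))
    return calls


def merge_pair_calls(
    r1_calls: Iterable[CpGCall], r2_calls: Iterable[CpGCall]
) -> list[CpGCall]:
    """Merge the two mates' calls with first-read precedence.

    The output covers the union of CpG offsets; where both mates cover
    a CpG, the R1 call is kept and the R2 call discarded, so each
    offset appears at most once per pair.
    """
    merged: dict[int, CpGCall] = {}
    assay_seen: str | None = None
    for call in r1_calls:
        assay_seen = assay_seen or call.assay
        if call.assay != assay_seen:
            raise ValueError(f"mixed assays in pair: {assay_seen} vs {call.assay}")
        merged[call.cpg_offset] = call
    for call in r2_calls:
        if assay_seen is None:
            assay_seen = call.assay
        elif call.assay != assay_seen:
            raise ValueError(f"mixed assays in pair: {assay_seen} vs {call.assay}")
        merged.setdefault(call.cpg_offset, call)
    return [merged[o] for o in sorted(merged)]


def fraction_methylated(count_c: int, count_t: int) -> float:
    """Methylated fraction ``count_c / (count_c + count_t)``.

    Ambiguous calls are excluded from the denominator. A zero
    denominator yields NaN (undefined-marked), never an exception.
    """
    if count_c < 0 or count_t < 0:
        raise ValueError("counts must be non-negative")
    total = count_c + count_t
    if total == 0:
        return math.nan
    return count_c / total


class MethylationAccumulator:
    """Accumulates merged calls into a per-sample x assay x CpG matrix.

    Also tallies conversion-evidence counts: at non-CpG cytosine
    reference positions a converted (unmethylated) template reads T, so
    the T fraction there estimates per-sample bisulfite conversion
    efficiency.
    """

    def __init__(self) -> None:
        # (sample, assay, cpg_offset) -> [count_c, count_t, count_ambiguous]
        self._cells: dict[tuple[str, str, int], list[int]] = {}
        # sample -> [n_T, n_C] at non-CpG-C positions
        self._conversion: dict[str, list[int]] = {}

    def add_calls(self, sample: str, calls: Iterable[CpGCall]) -> None:
        for call in calls:
            cell = self._cells.setdefault((sample, call.assay, call.cpg_offset), [0, 0, 0])
            if call.state == METHYLATED:
                cell[0] += 1
            elif call.state == UNMETHYLATED:
                cell[1] += 1
            else:
                cell[2] += 1

    def add_counts(
        self,
        sample: str,
        assay: str,
        cpg_offset: int,
        count_c: int,
        count_t: int,
        count_ambiguous: int = 0,
    ) -> None:
        """Bulk entry point used by the vectorized pipeline."""
        cell = self._cells.setdefault((sample, assay, cpg_offset), [0, 0, 0])
        cell[0] += count_c
        cell[1] += count_t
        cell[2] += count_ambiguous

    def add_conversion_evidence(self, sample: str, n_t: int, n_c: int) -> None:
        ev = self._conversion.setdefault(sample, [0, 0])
        ev[0] += n_t
        ev[1] += n_c

    def ensure_cell(self, sample: str, assay: str, cpg_offset: int) -> None:
        """Register a CpG cell even if no calls land there (keeps zero rows)."""
        self._cells.setdefault((sample, assay, cpg_offset), [0, 0, 0])

    def to_matrix(self) -> pd.DataFrame:
        """Long-format methylation matrix, one row per CpG cell."""
        rows = [
            (s, a, o, c[0], c[1], c[2], fraction_methylated(c[0], c[1]))
            for (s, a, o), c in sorted(self._cells.items())
        ]
        return pd.DataFrame(rows, columns=MATRIX_COLUMNS)

    def conversion_efficiency(self, sample: str) -> float:
        """Estimated conversion rate for a sample, NaN when uninformative."""
        n_t, n_c = self._conversion.get(sample, (0, 0))
        return conversion_efficiency_from_counts(n_t, n_c)

    def conversion_table(self) -> pd.DataFrame:
        rows = [
            (s, ev[0], ev[1], conversion_efficiency_from_counts(ev[0], ev[1]))
            for s, ev in sorted(self._conversion.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample", "converted_t", "unconverted_c", "conversion_efficiency"]
        )


def conversion_efficiency_from_counts(n_t: int, n_c: int) -> float:
    """Fraction read as T among {C, T} at non-CpG cytosine positions."""
    total = n_t + n_c
    if total == 0:
        return math.nan
    return n_t / total


def conversion_efficiency(
    alignments: Iterable[AmpliconAlignment], assay: TargetAssay
) -> float:
    """Estimate bisulfite conversion efficiency from aligned reads.

    Non-CpG cytosines outside primer footprints should always read T
    after complete conversion, whatever the CpG methylation state; the
    fraction observed as T among {C, T} observations at those reference
    positions estimates the conversion rate. NaN when the assay has no
    informative position or no read covers one (undefined-marked).
    """
    informative = assay.non_cpg_c_offsets()
    n_t = n_c = 0
    for aln in alignments:
        for o in informative:
            if not aln.covers(o) or o in aln.masked:
                continue
            base = aln.base_at(o)
            if base == "T":
                n_t += 1
            elif base == "C":
                n_c += 1
    return conversion_efficiency_from_counts(n_t, n_c)


def coverage_filter(matrix: pd.DataFrame, min_calls: int) -> pd.DataFrame:
    """Undefined-mark CpG cells with fewer than ``min_calls`` informative calls.

    Counts are retained for reporting; only ``fraction`` is set to NaN.
    ``min_calls=0`` is the identity.
    """
    if min_calls < 0:
        raise ValueError("min_calls must be >= 0")
    out = matrix.copy()
    low = (out["count_c"] + out["count_t"]) < min_calls
    out.loc[low, "fraction"] = np.nan
    return out
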