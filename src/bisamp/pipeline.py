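"""End-to-end pipeline: assign -> align -> call -> merge -> QC -> compare.

The per-sample stages run on a vectorized batch path (NumPy byte
arrays) whose contract is identical to the scalar operations in
:mod:`bisamp.align` and :mod:`bisamp.methcall`; the test suite asserts
the two paths agree call-for-call. All placements are exhaustive
minimum-mismatch scans in the reduced alphabet, with the first-read-
precedence overlap rule applied per pair before counts are
accumulated.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .align import (
    AlignmentConfig,
    batch_assign_pairs,
    batch_min_mismatch_offsets,
    encode_seq,
    reduce_alphabet,
)
from .assay import TargetAssay
from .io import FastqRecord, RunConfig, load_panel, read_fastq_pairs, read_sample_sheet
from .methcall import MethylationAccumulator, coverage_filter
from .simulate import _COMP_U8  # byte-level complement table
from .stats import AllocationReport, GroupComparison, compare_groups, read_allocation_report

__all__ = [
    "SampleCounts",
    "PipelineResult",
    "process_sample_pairs",
    "run_study",
    "run_pipeline",
    "write_bedgraph",
]

logger = logging.getLogger("bisamp")

_C = ord("C")
_T = ord("T")


@dataclass
class SampleCounts:
    """Per-sample tallies produced by the batch path."""

    sample_id: str
    n_pairs: int
    assigned_per_assay: dict[str, int]
    n_unassigned_ceiling: int
    n_unassigned_tie: int
    n_rejected_alignment: int


@dataclass
class PipelineResult:
    """In-memory results of a full study run."""

    matrix: pd.DataFrame
    conversion: pd.DataFrame
    allocation: AllocationReport
    comparison: GroupComparison | None
    sample_counts: list[SampleCounts]


def _encode_block(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 array."""
    joined = "".join(seqs).encode("ascii")
    arr = np.frombuffer(joined, dtype=np.uint8)
    return arr.reshape(len(seqs), -1).copy()


def _reduce_u8(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == _C] = _T
    return out


def process_sample_pairs(
    sample_id: str,
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    panel: Sequence[TargetAssay],
    acc: MethylationAccumulator,
    config: AlignmentConfig | None = None,
    mask_primer_cpgs: bool = True,
) -> SampleCounts:
    """Assign, align, and call every read pair of one sample.

    Pairs are grouped by mate lengths and processed as byte matrices:
    assignment by total reduced-alphabet mismatch against each
    amplicon's prefix/suffix, then exhaustive min-mismatch placement on
    the winning amplicon, then per-CpG calling with R1 precedence in
    mate overlaps. Counts accumulate into ``acc``.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    if config is None:
        config = AlignmentConfig()

    # Pre-register all reportable cells so zero-coverage CpGs keep rows.
    for assay in panel:
        for o in assay.cpg_offsets:
            if mask_primer_cpgs and assay.in_footprint(o):
                continue
            acc.ensure_cell(sample_id, assay.name, o)

    by_len: dict[tuple[int, int], tuple[list[str], list[str]]] = {}
    n_pairs = 0
    for (t1, s1, q1), (t2, s2, q2) in pairs:
        n_pairs += 1
        key = (len(s1), len(s2))
        r1s, r2s = by_len.setdefault(key, ([], []))
        r1s.append(s1.upper())
        r2s.append(s2.upper())

    counts = SampleCounts(sample_id, n_pairs, {a.name: 0 for a in panel}, 0, 0, 0)
    for (l1, l2), (r1s, r2s) in by_len.items():
        r1 = _encode_block(r1s)
        r2_oriented = _COMP_U8[_encode_block(r2s)][:, ::-1].copy()
        r1_red = _reduce_u8(r1)
        r2_red = _reduce_u8(r2_oriented)
        assay_idx, reason = batch_assign_pairs(r1_red, r2_red, panel, config)
        counts.n_unassigned_ceiling += int((reason == 1).sum())
        counts.n_unassigned_tie += int((reason == 2).sum())
        for k, assay in enumerate(panel):
            rows = np.nonzero(assay_idx == k)[0]
            if len(rows) == 0:
                continue
            counts.assigned_per_assay[assay.name] += len(rows)
            rej = _call_assay_block(
                sample_id,
                assay,
                r1[rows],
                r1_red[rows],
                r2_oriented[rows],
                r2_red[rows],
                acc,
                config,
                mask_primer_cpgs,
            )
            counts.n_rejected_alignment += rej
    return counts


def _call_assay_block(
    sample_id: str,
    assay: TargetAssay,
    r1: np.ndarray,
    r1_red: np.ndarray,
    r2: np.ndarray,
    r2_red: np.ndarray,
    acc: MethylationAccumulator,
    config: AlignmentConfig,
    mask_primer_cpgs: bool,
) -> int:
    """Align one assay's assigned pairs and accumulate CpG calls.

    Returns the number of mates rejected at the mismatch ceiling.
    """
    ref_red = encode_seq(reduce_alphabet(assay.region_seq))
    L = len(ref_red)

    def _place(red: np.ndarray, orig: np.ndarray, anchor_end: bool):
        l = red.shape[1]
        if l > L:  # read-through beyond the amplicon: anchor by truncation
            sl = slice(-L, None) if anchor_end else slice(0, L)
            red, orig = red[:, sl], orig[:, sl]
            l = L
        off, mm = batch_min_mismatch_offsets(red, ref_red)
        ok = mm <= config.mismatch_ceiling(l)
        return off, ok, orig, l

    off1, ok1, r1o, l1 = _place(r1_red, r1, anchor_end=False)
    off2, ok2, r2o, l2 = _place(r2_red, r2, anchor_end=True)
    n = r1o.shape[0]
    rejected = int((~ok1).sum() + (~ok2).sum())

    def _gather(offsets, ok, orig, l, pos):
        col = pos - offsets
        valid = ok & (col >= 0) & (col < l)
        safe = np.clip(col, 0, l - 1)
        return orig[np.arange(n), safe], valid

    for o in assay.cpg_offsets:
        if mask_primer_cpgs and assay.in_footprint(o):
            continue
        b1, v1 = _gather(off1, ok1, r1o, l1, o)
        b2, v2 = _gather(off2, ok2, r2o, l2, o)
        # R1 precedence: R2 contributes only where R1 does not cover.
        base = np.where(v1, b1, b2)
        used = v1 | v2
        n_c = int(((base == _C) & used).sum())
        n_t = int(((base == _T) & used).sum())
        n_x = int(used.sum()) - n_c - n_t
        acc.add_counts(sample_id, assay.name, o, n_c, n_t, n_x)

    conv_t = conv_c = 0
    for o in assay.non_cpg_c_offsets():
        b1, v1 = _gather(off1, ok1, r1o, l1, o)
        b2, v2 = _gather(off2, ok2, r2o, l2, o)
        base = np.where(v1, b1, b2)
        used = v1 | v2
        conv_c += int(((base == _C) & used).sum())
        conv_t += int(((base == _T) & used).sum())
    acc.add_conversion_evidence(sample_id, conv_t, conv_c)
    return rejected


def run_study(
    panel: Sequence[TargetAssay],
    sample_sheet: pd.DataFrame,
    align_config: AlignmentConfig | None = None,
    mask_primer_cpgs: bool = True,
    min_coverage: int = 0,
    alpha: float = 0.05,
    correction: str | None = None,
    welch: bool = False,
    compare: bool = True,
) -> PipelineResult:
    """Run the full pipeline over every sample of a sheet, in memory."""
    acc = MethylationAccumulator()
    sample_counts = []
    for _, row in sample_sheet.iterrows():
        pairs = read_fastq_pairs(row["r1_path"], row["r2_path"])
        sc = process_sample_pairs(
            row["sample_id"], pairs, panel, acc, align_config, mask_primer_cpgs
        )
        sample_counts.append(sc)
        logger.info(
            "sample %s: %d pairs, %d unassigned (ceiling %d, tie %d)",
            sc.sample_id,
            sc.n_pairs,
            sc.n_unassigned_ceiling + sc.n_unassigned_tie,
            sc.n_unassigned_ceiling,
            sc.n_unassigned_tie,
        )
    matrix = acc.to_matrix()
    if min_coverage > 0:
        matrix = coverage_filter(matrix, min_coverage)
    conversion = acc.conversion_table()
    alloc_rows = [
        (sc.sample_id, assay, reads)
        for sc in sample_counts
        for assay, reads in sc.assigned_per_assay.items()
    ]
    allocation = read_allocation_report(
        pd.DataFrame(alloc_rows, columns=["sample", "assay", "reads"])
    )
    comparison = None
    if compare and sample_sheet["group"].nunique() == 2:
        comparison = compare_groups(
            matrix,
            sample_sheet,
            alpha=alpha,
            correction=correction or None,
            welch=welch,
        )
    return PipelineResult(matrix, conversion, allocation, comparison, sample_counts)


def _positions_for(matrix_like: pd.DataFrame, panel: Sequence[TargetAssay]) -> pd.DataFrame:
    """Attach chrom and 1-based genomic CpG position columns."""
    intervals = {a.name: a.interval for a in panel}
    out = matrix_like.copy()
    out["chrom"] = out["assay"].map(lambda a: intervals[a].chrom)
    out["position"] = [
        intervals[a].start + int(o) if pd.notna(o) else pd.NA
        for a, o in zip(out["assay"], out["cpg_offset"])
    ]
    return out


def write_bedgraph(
    matrix: pd.DataFrame, panel: Sequence[TargetAssay], sample: str, path: str | Path
) -> None:
    """Per-sample bedGraph of methylation fractions (0-based half-open)."""
    intervals = {a.name: a.interval for a in panel}
    sub = matrix[(matrix["sample"] == sample) & matrix["fraction"].notna()]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{sample} methylation"\n')
        for _, row in sub.iterrows():
            iv = intervals[row["assay"]]
            start0 = iv.start - 1 + int(row["cpg_offset"])
            fh.write(f"{iv.chrom}\t{start0}\t{start0 + 1}\t{row['fraction']:.6g}\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the whole pipeline from a run configuration.

    Stages: load panel and sheet -> per-sample assign/align/call/merge
    -> accumulate -> QC -> two-group comparison -> write TSV/JSON
    outputs plus a log of versions, seed, and parameters. Returns the
    output directory; any stage error propagates after being logged.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("bisamp %s | python %s", __version__, sys.version.split()[0])
        logger.info("config: %s", config)
        config.to_file(outdir / "run_config.txt")
        panel = load_panel(config.panel_fasta, config.panel_bed, config.panel_primers)
        sheet = read_sample_sheet(config.sample_sheet, check_files=True)
        result = run_study(
            panel,
            sheet,
            AlignmentConfig(config.max_mismatch_frac, config.assignment_margin),
            mask_primer_cpgs=config.mask_primer_cpgs,
            min_coverage=config.min_coverage,
            alpha=config.alpha,
            correction=config.correction or None,
            welch=config.welch,
        )
        matrix_out = _positions_for(result.matrix, panel)
        matrix_out.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
        result.conversion.to_csv(outdir / "conversion.tsv", sep="\t", index=False)
        result.allocation.per_sample.to_csv(
            outdir / "allocation_per_sample.tsv", sep="\t", index=False
        )
        result.allocation.per_cell.to_csv(
            outdir / "allocation_per_cell.tsv", sep="\t", index=False
        )
        qc = {
            "total_assigned": result.allocation.total_assigned,
            "expected_reads_per_amplicon_sample": result.allocation.expected_per_cell,
            "samples": {
                sc.sample_id: {
                    "pairs": sc.n_pairs,
                    "unassigned_ceiling": sc.n_unassigned_ceiling,
                    "unassigned_tie": sc.n_unassigned_tie,
                    "rejected_alignments": sc.n_rejected_alignment,
                }
                for sc in result.sample_counts
            },
        }
        (outdir / "qc.json").write_text(json.dumps(qc, indent=2) + "\n")
        if result.comparison is not None:
            comp = _positions_for(result.comparison.table, panel)
            comp.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        for sample in sheet["sample_id"]:
            write_bedgraph(
                result.matrix, panel, sample, outdir / f"{sample}.bedgraph"
            )
        logger.info("run complete: %s", outdir)
        return outdir
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
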