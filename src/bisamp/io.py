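"""Readers, writers, sample sheets, barcodes, and demultiplexing.

Standard plain-text formats only: 4-line FASTQ (optionally gzip),
FASTA + BED + primer TSV for panels, TSV sample sheets, and a flat
``key = value`` run-configuration format that is serialized verbatim
into every output directory.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .assay import GenomicInterval, TargetAssay

__all__ = [
    "FastqPairError",
    "read_fastq_pairs",
    "write_fastq",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_panel",
    "write_panel",
    "default_barcodes",
    "demultiplex",
    "RunConfig",
]

FastqRecord = tuple[str, str, str]  # (title, sequence, quality)


class FastqPairError(ValueError):
    """Malformed or mismatched paired FASTQ input."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Stream read pairs from two (optionally gzipped) FASTQ files.

    Records are matched positionally, in file order. A record-count
    mismatch raises :class:`FastqPairError` naming the pair index at
    which one file ran out.
    """
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = r1_path if rec1 is None else r2_path
                raise FastqPairError(
                    f"record count mismatch: {short} exhausted at pair index {index}"
                )
            yield rec1, rec2
            index += 1


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    """Write 4-line FASTQ records; gzip when the path ends in .gz."""
    with _open_text(path, "wt") as handle:
        for title, seq, qual in records:
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "index", "r1_path", "r2_path"]


def read_sample_sheet(path: str | Path, check_files: bool = False) -> pd.DataFrame:
    """Load and validate a TSV sample sheet.

    Requires unique sample ids and unique index barcodes; with
    ``check_files=True`` every referenced FASTQ path must exist.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if sheet["index"].duplicated().any():
        dupes = sheet.loc[sheet["index"].duplicated(), "index"].tolist()
        raise ValueError(f"duplicate index barcodes: {dupes}")
    if check_files:
        for _, row in sheet.iterrows():
            for col in ("r1_path", "r2_path"):
                if not Path(row[col]).exists():
                    raise FileNotFoundError(
                        f"sample {row['sample_id']}: missing {col} {row[col]}"
                    )
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Panels (FASTA of regions + BED of intervals + primer TSV)
# ---------------------------------------------------------------------------


def load_panel(
    fasta_path: str | Path, bed_path: str | Path, primers_path: str | Path
) -> list[TargetAssay]:
    """Assemble a panel from region FASTA, interval BED, and primer TSV.

    FASTA record ids are assay names; the BED (0-based half-open, name
    in column 4) is converted to 1-based closed intervals on load; the
    primer TSV has columns (name, fwd, rev). Every FASTA record must
    have a matching BED line and primer row.
    """
    regions = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not regions:
        raise ValueError(f"no FASTA records in {fasta_path}")
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    intervals = {
        row["name"]: GenomicInterval.from_bed(
            str(row["chrom"]), int(row["start"]), int(row["end"]),
            str(row["strand"]) if pd.notna(row["strand"]) else "+",
        )
        for _, row in bed.iterrows()
    }
    primers = pd.read_csv(primers_path, sep="\t", dtype=str)
    for col in ("name", "fwd", "rev"):
        if col not in primers.columns:
            raise ValueError(f"primer TSV missing column {col!r}")
    primer_map = {row["name"]: (row["fwd"].upper(), row["rev"].upper())
                  for _, row in primers.iterrows()}
    panel = []
    for name, seq in regions.items():
        if name not in intervals:
            raise ValueError(f"assay {name!r} missing from BED {bed_path}")
        if name not in primer_map:
            raise ValueError(f"assay {name!r} missing from primer TSV {primers_path}")
        fwd, rev = primer_map[name]
        panel.append(
            TargetAssay(
                name=name,
                interval=intervals[name],
                region_seq=seq,
                fwd_primer=fwd,
                rev_primer=rev,
            )
        )
    return panel


def write_panel(panel: Sequence[TargetAssay], outdir: str | Path) -> dict[str, Path]:
    """Write a panel as regions.fa + regions.bed + primers.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "regions.fa"
    bed = outdir / "regions.bed"
    primers = outdir / "primers.tsv"
    with open(fasta, "w") as fh:
        for assay in panel:
            fh.write(f">{assay.name}\n{assay.region_seq}\n")
    with open(bed, "w") as bh:
        for assay in panel:
            chrom, start0, end0, strand = assay.interval.to_bed()
            bh.write(f"{chrom}\t{start0}\t{end0}\t{assay.name}\t0\t{strand}\n")
    with open(primers, "w") as ph:
        ph.write("name\tfwd\trev\n")
        for assay in panel:
            ph.write(f"{assay.name}\t{assay.fwd_primer}\t{assay.rev_primer}\n")
    return {"fasta": fasta, "bed": bed, "primers": primers}


# ---------------------------------------------------------------------------
# Index barcodes and demultiplexing
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def default_barcodes(n: int = 48, length: int = 6, min_distance: int = 3) -> list[str]:
    """Deterministic set of single-index barcodes.

    Greedy selection over lexicographic 6-mers keeping pairwise Hamming
    distance >= ``min_distance`` (so single sequencing errors cannot
    turn one valid barcode into another) and skipping homopolymers.
    """
    chosen: list[str] = []
    for combo in itertools.product("ACGT", repeat=length):
        candidate = "".join(combo)
        if len(set(candidate)) == 1:
            continue
        if all(_hamming(candidate, c) >= min_distance for c in chosen):
            chosen.append(candidate)
        if len(chosen) == n:
            return chosen
    raise ValueError(f"cannot build {n} barcodes of length {length}")


def demultiplex(
    indexed_pairs: Iterable[tuple[str, tuple[FastqRecord, FastqRecord]]],
    sample_sheet: pd.DataFrame,
    max_index_mismatch: int = 1,
) -> dict[str, list[tuple[FastqRecord, FastqRecord]]]:
    """Split (index, read-pair) records into per-sample bins.

    A pair goes to the unique sample whose barcode is within
    ``max_index_mismatch``; ties between samples or no match within the
    threshold go to the ``"undetermined"`` bin.
    """
    if sample_sheet["index"].duplicated().any():
        raise ValueError("duplicate index barcodes in sample sheet")
    barcodes = list(zip(sample_sheet["sample_id"], sample_sheet["index"]))
    bins: dict[str, list[tuple[FastqRecord, FastqRecord]]] = {
        sid: [] for sid, _ in barcodes
    }
    bins["undetermined"] = []
    for index_seq, pair in indexed_pairs:
        dists = [(_hamming(index_seq, bc), sid) for sid, bc in barcodes]
        dists.sort(key=lambda t: t[0])
        best_d, best_sid = dists[0]
        tie = len(dists) > 1 and dists[1][0] == best_d
        if best_d <= max_index_mismatch and not tie:
            bins[best_sid].append(pair)
        else:
            bins["undetermined"].append(pair)
    return bins


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything the pipeline needs for one run.

    Serialized verbatim (``key = value`` per line) into the output
    directory so any run can be reproduced from its artifacts alone.
    """

    panel_fasta: str = ""
    panel_bed: str = ""
    panel_primers: str = ""
    sample_sheet: str = ""
    outdir: str = "bisamp_out"
    max_mismatch_frac: float = 0.10
    assignment_margin: int = 5
    min_coverage: int = 0
    mask_primer_cpgs: bool = True
    alpha: float = 0.05
    correction: str = ""
    welch: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.max_mismatch_frac <= 1.0:
            raise ValueError("max_mismatch_frac must be in [0, 1]")
        if self.assignment_margin < 0:
            raise ValueError("assignment_margin must be >= 0")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("", "bh"):
            raise ValueError("correction must be '' or 'bh'")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in ("true", "1", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)  # type: ignore[arg-type]
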