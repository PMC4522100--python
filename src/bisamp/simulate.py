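"""Simulation of paired-end bisulfite amplicon reads with ground truth.

Emulates a targeted bisulfite sequencing study of five amplicons
(153-298 bp) across ten barcoded samples in two groups of five, with
150 bp paired-end reads: per-molecule CpG methylation states, incomplete
bisulfite conversion, and uniform per-base sequencing errors. Every
draw is tied to an explicit seed, and a truth table records the
realized per-CpG counts so the whole pipeline can be validated without
any external data.

The conversion model per molecule: a CpG cytosine survives as C if the
molecule is methylated there (probability m) or if conversion failed
(probability 1 - lambda on an unmethylated molecule), so the expected
observed C fraction at a CpG is ``m + (1 - m) * (1 - lambda)``. Every
non-CpG cytosine reads C only on conversion failure (probability
1 - lambda).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import (
    GenomicInterval,
    TargetAssay,
    bisulfite_convert,
    reverse_complement,
)

__all__ = [
    "SimProfile",
    "SimulatedSample",
    "StudyOutput",
    "simulate_molecule",
    "simulate_sample_reads",
    "simulate_study",
    "islet_demo_panel",
    "islet_study_profiles",
    "flat_profile",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "sample",
    "assay",
    "cpg_offset",
    "true_m",
    "molecules",
    "methylated_molecules",
    "conversion_failures",
]

_BASES = "ACGT"
_BASE2IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE2IDX[ord(_b)] = _i
_IDX2BASE = np.frombuffer(_BASES.encode(), dtype=np.uint8)
_COMP_U8 = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_U8[_a] = _b


@dataclass(frozen=True)
class SimProfile:
    """Study conditions for one simulated group of samples.

    Attributes
    ----------
    methylation
        Per-assay true methylation: assay name -> per-CpG probability
        array (a scalar is broadcast over the assay's CpGs).
    conversion_rate
        Probability lambda that an unmethylated C is converted (read as
        T). Commercial bisulfite kits convert nearly completely; 0.995
        is a realistic default.
    error_rate
        Per-base substitution probability, uniform over the three other
        bases. 0.1% approximates a well-behaved short-read run.
    read_length
        Mate length in bp (150, paired-end).
    n_pairs
        Read pairs per amplicon per sample (200,000 matches the
        per-amplicon-per-sample depth of the study design this
        simulator emulates; tests use far less).
    """

    methylation: Mapping[str, float | Sequence[float]]
    conversion_rate: float = 0.995
    error_rate: float = 0.001
    read_length: int = 150
    n_pairs: int = 200_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        for name, m in self.methylation.items():
            arr = np.atleast_1d(np.asarray(m, dtype=float))
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"methylation for {name!r} outside [0, 1]")

    def cpg_m(self, assay: TargetAssay) -> np.ndarray:
        """Per-CpG methylation probabilities for one assay."""
        m = np.atleast_1d(np.asarray(self.methylation[assay.name], dtype=float))
        if m.size == 1:
            m = np.full(len(assay.cpg_offsets), float(m[0]))
        if m.size != len(assay.cpg_offsets):
            raise ValueError(
                f"{assay.name}: {m.size} methylation values for "
                f"{len(assay.cpg_offsets)} CpGs"
            )
        return m


def flat_profile(
    panel: Sequence[TargetAssay], m: float, **kwargs
) -> SimProfile:
    """A profile with the same true methylation at every CpG of every assay."""
    return SimProfile(methylation={a.name: m for a in panel}, **kwargs)


# ---------------------------------------------------------------------------
# Molecule-level simulation
# ---------------------------------------------------------------------------


def simulate_molecule(
    assay: TargetAssay, profile: SimProfile, rng: np.random.Generator
) -> str:
    """Draw one converted top-strand molecule for an amplicon.

    Each CpG cytosine is retained as C with probability
    ``m + (1 - m)(1 - lambda)``; every other C is retained with
    probability ``1 - lambda``, else converted to T; non-C bases are
    unchanged.
    """
    m = profile.cpg_m(assay)
    lam = profile.conversion_rate
    cpg = dict(zip(assay.cpg_offsets, m))
    out = []
    for i, base in enumerate(assay.region_seq):
        if base != "C":
            out.append(base)
            continue
        if i in cpg:
            methylated = rng.random() < cpg[i]
            keep_c = methylated or rng.random() < (1.0 - lam)
        else:
            keep_c = rng.random() < (1.0 - lam)
        out.append("C" if keep_c else "T")
    return "".join(out)


def _simulate_molecules_batch(
    assay: TargetAssay, profile: SimProfile, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n converted molecules as a (n, L) uint8 array.

    Returns (molecules, methylated_per_cpg, conversion_failures_per_cpg)
    where the two count vectors are per-CpG realized totals.
    """
    seq = np.frombuffer(assay.region_seq.encode(), dtype=np.uint8)
    mol = np.tile(seq, (n, 1))
    lam = profile.conversion_rate
    cpg = np.asarray(assay.cpg_offsets, dtype=np.intp)
    m = profile.cpg_m(assay)
    if n == 0:
        k = len(cpg)
        return mol, np.zeros(k, dtype=np.int64), np.zeros(k, dtype=np.int64)
    if len(cpg):
        methylated = rng.random((n, len(cpg))) < m
        failed = rng.random((n, len(cpg))) < (1.0 - lam)
        keep_c = methylated | failed
        cols = mol[:, cpg]
        cols[~keep_c] = ord("T")
        mol[:, cpg] = cols
        meth_counts = methylated.sum(axis=0)
        fail_counts = (failed & ~methylated).sum(axis=0)
    else:
        meth_counts = np.zeros(0, dtype=np.int64)
        fail_counts = np.zeros(0, dtype=np.int64)
    other_c = np.asarray(
        [i for i, b in enumerate(assay.region_seq)
         if b == "C" and i not in set(assay.cpg_offsets)],
        dtype=np.intp,
    )
    if len(other_c):
        failed_other = rng.random((n, len(other_c))) < (1.0 - lam)
        cols = mol[:, other_c]
        cols[~failed_other] = ord("T")
        mol[:, other_c] = cols
    return mol, meth_counts, fail_counts


def _apply_errors(
    reads: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute bases at ``error_rate``, uniformly among the 3 others."""
    if error_rate <= 0.0 or reads.size == 0:
        return reads
    hit = rng.random(reads.shape) < error_rate
    if not hit.any():
        return reads
    shift = rng.integers(1, 4, size=int(hit.sum()))
    idx = _BASE2IDX[reads[hit]]
    reads[hit] = _IDX2BASE[(idx + shift) % 4]
    return reads


def _revcomp_rows(arr: np.ndarray) -> np.ndarray:
    return _COMP_U8[arr][:, ::-1]


@dataclass
class SimulatedSample:
    """Reads and truth for one sample: parallel R1/R2 record lists."""

    sample_id: str
    r1_records: list[tuple[str, str, str]]
    r2_records: list[tuple[str, str, str]]
    truth: pd.DataFrame


def simulate_sample_reads(
    panel: Sequence[TargetAssay],
    profile: SimProfile,
    sample_id: str,
    rng: np.random.Generator,
) -> SimulatedSample:
    """Simulate all read pairs of one sample across a panel.

    R1 is the first ``read_length`` bases of each converted molecule
    (left-primer strand); R2 is the reverse complement of the last
    ``read_length`` bases; both are truncated to the molecule length
    for short amplicons. Per-base substitution errors are applied at
    the profile's rate; qualities are a constant placeholder; record
    ids encode sample, assay, and molecule index.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    r1_records: list[tuple[str, str, str]] = []
    r2_records: list[tuple[str, str, str]] = []
    truth_rows = []
    for assay in panel:
        n = profile.n_pairs
        mol, meth_counts, fail_counts = _simulate_molecules_batch(
            assay, profile, n, rng
        )
        read_len = min(profile.read_length, assay.region_length)
        r1 = mol[:, :read_len].copy()
        r2 = _revcomp_rows(mol[:, assay.region_length - read_len :]).copy()
        r1 = _apply_errors(r1, profile.error_rate, rng)
        r2 = _apply_errors(r2, profile.error_rate, rng)
        qual = "I" * read_len
        for i in range(n):
            rid = f"{sample_id}:{assay.name}:{i}"
            r1_records.append((f"{rid}/1", r1[i].tobytes().decode("ascii"), qual))
            r2_records.append((f"{rid}/2", r2[i].tobytes().decode("ascii"), qual))
        m = profile.cpg_m(assay)
        for j, o in enumerate(assay.cpg_offsets):
            truth_rows.append(
                (
                    sample_id,
                    assay.name,
                    o,
                    float(m[j]),
                    n,
                    int(meth_counts[j]) if n else 0,
                    int(fail_counts[j]) if n else 0,
                )
            )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedSample(sample_id, r1_records, r2_records, truth)


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------


@dataclass
class StudyOutput:
    """File layout of one simulated study."""

    outdir: Path
    sample_sheet_path: Path
    truth_path: Path
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame


def simulate_study(
    panel: Sequence[TargetAssay],
    group_profiles: Mapping[str, SimProfile],
    n_per_group: int,
    seed: int,
    outdir: str | Path,
    gzip_fastq: bool = False,
) -> StudyOutput:
    """Simulate a full multi-sample two-or-more-group study to disk.

    Writes one FASTQ pair per sample, a sample sheet (sample_id, group,
    6-nt index, file paths), and a truth table. Fully deterministic
    under a fixed seed: each sample's generator is derived from
    ``(seed, sample_ordinal)``.
    """
    from .io import default_barcodes, write_fastq, write_sample_sheet

    if not panel:
        raise ValueError("panel must be nonempty")
    if len(group_profiles) < 2:
        raise ValueError("at least two groups required")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sample_ids = [
        f"{group}_{i + 1}"
        for group in group_profiles
        for i in range(n_per_group)
    ]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids: {sample_ids}")
    barcodes = default_barcodes(len(sample_ids))

    sheet_rows = []
    truth_frames = []
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    ordinal = 0
    for group, profile in group_profiles.items():
        for i in range(n_per_group):
            sample_id = f"{group}_{i + 1}"
            rng = np.random.default_rng([seed, ordinal])
            sim = simulate_sample_reads(panel, profile, sample_id, rng)
            r1_path = outdir / f"{sample_id}_R1{ext}"
            r2_path = outdir / f"{sample_id}_R2{ext}"
            write_fastq(sim.r1_records, r1_path)
            write_fastq(sim.r2_records, r2_path)
            sheet_rows.append(
                (sample_id, group, barcodes[ordinal], str(r1_path), str(r2_path))
            )
            truth_frames.append(sim.truth)
            ordinal += 1

    sample_sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "group", "index", "r1_path", "r2_path"]
    )
    truth = pd.concat(truth_frames, ignore_index=True)
    sheet_path = outdir / "sample_sheet.tsv"
    truth_path = outdir / "truth.tsv"
    write_sample_sheet(sample_sheet, sheet_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    return StudyOutput(outdir, sheet_path, truth_path, sample_sheet, truth)


# ---------------------------------------------------------------------------
# Built-in demo panel emulating the five-locus human-islet study design
# ---------------------------------------------------------------------------

# Table of (name, chrom, start, end, region_len, n_cpgs, fwd_len, rev_len).
# Coordinates and region lengths follow the published five-amplicon islet
# panel (hg19); region lengths are authoritative where the two disagree.
_DEMO_LOCI = [
    ("MEG3", "chr14", 101_291_952, 101_292_257, 298, 19, 25, 21),
    ("INS", "chr11", 2_182_551, 2_182_775, 225, 4, 24, 22),
    ("IRS1", "chr2", 227_659_611, 227_659_781, 171, 3, 23, 22),
    ("CDKN1A", "chr6", 36_645_462, 36_645_696, 235, 3, 24, 23),
    ("PDE7B", "chr6", 136_172_765, 136_172_917, 153, 3, 22, 21),
]

# Published MEG3 primer pair (bisulfite space); both are C-free, so the
# corresponding genomic footprints can be taken verbatim.
_MEG3_FWD = "GGGGTGATAGTTTTTGGTTTATATT"
_MEG3_REV = "CCATAACCAACACCCTATAAT"

_PANEL_SEED = 20150801  # fixed: the demo panel is a constant, like a genome


def _synthesize_region(
    rng: np.random.Generator,
    length: int,
    n_cpgs: int,
    fwd_len: int,
    rev_len: int,
    prefix: str | None = None,
    suffix: str | None = None,
) -> str:
    """Random region sequence with exactly ``n_cpgs`` CpGs, all outside
    C-free primer footprints."""
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    # Primer footprints: no cytosine, so bisulfite conversion leaves the
    # primer-binding sites unambiguous.
    for i in range(fwd_len):
        if seq[i] == "C":
            seq[i] = "T"
    for i in range(length - rev_len, length):
        if seq[i] == "C":
            seq[i] = "A"
    if prefix is not None:
        seq[: len(prefix)] = list(prefix)
    if suffix is not None:
        seq[length - len(suffix) :] = list(suffix)
    # Scrub accidental CpGs, then plant the requested ones evenly spaced
    # in the footprint-free interior.
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    lo, hi = fwd_len + 2, length - rev_len - 3
    positions = np.unique(np.linspace(lo, hi, n_cpgs).round().astype(int))
    if len(positions) != n_cpgs or (np.diff(positions) < 3).any():
        raise ValueError("region too short for requested CpG count")
    for p in positions:
        seq[p], seq[p + 1] = "C", "G"
        if seq[p - 1] == "C":
            seq[p - 1] = "T"
    out = "".join(seq)
    found = [i for i in range(len(out) - 1) if out[i : i + 2] == "CG"]
    assert found == list(positions), "CpG planting failed"
    return out


def islet_demo_panel() -> list[TargetAssay]:
    """The built-in five-amplicon demo panel.

    Mirrors the published human-islet panel in its printed genomic
    coordinates, region lengths (153-298 bp), and per-amplicon CpG
    counts (MEG3 19, INS 4, IRS1 3, CDKN1A 3, PDE7B 3); MEG3 carries
    the published primer pair verbatim. The region SEQUENCES are
    synthetic (deterministically generated, since no reference genome
    is bundled), so methylation positions are exact within each
    amplicon but do not correspond to real hg19 bases.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    panel = []
    for name, chrom, start, end, length, n_cpgs, fwd_len, rev_len in _DEMO_LOCI:
        prefix = suffix = None
        if name == "MEG3":
            prefix = _MEG3_FWD
            # rev primer anneals to the converted top strand: the genomic
            # suffix is its reverse complement (C-free, hence invariant).
            suffix = reverse_complement(_MEG3_REV)
            fwd_len, rev_len = len(_MEG3_FWD), len(_MEG3_REV)
        region = _synthesize_region(
            rng, length, n_cpgs, fwd_len, rev_len, prefix, suffix
        )
        fwd = bisulfite_convert(region[:fwd_len], protect_cpg=False)
        rev = reverse_complement(
            bisulfite_convert(region[length - rev_len :], protect_cpg=False)
        )
        panel.append(
            TargetAssay(
                name=name,
                interval=GenomicInterval(chrom, start, end),
                region_seq=region,
                fwd_primer=fwd,
                rev_primer=rev,
            )
        )
    return panel


def islet_study_profiles(
    n_pairs: int = 200_000,
    conversion_rate: float = 0.995,
    error_rate: float = 0.001,
    read_length: int = 150,
) -> dict[str, SimProfile]:
    """Default two-group study conditions emulating the islet panel.

    Group "ND" (non-diabetic-like) vs "T2D" (diabetic-like): MEG3
    region means 0.43 vs 0.61 with modest per-CpG spread; INS 0.24 vs
    0.46 at all four CpGs; IRS1 differs at its first CpG only (0.47 vs
    0.37); CDKN1A at its second and third (0.10 lower); PDE7B is null
    at all three CpGs.
    """

    def spread(mean: float, k: int, width: float = 0.04) -> np.ndarray:
        if k == 1:
            return np.array([mean])
        d = np.linspace(-width, width, k)
        return mean + d - d.mean()

    nd = {
        "MEG3": spread(0.43, 19),
        "INS": spread(0.24, 4, 0.03),
        "IRS1": np.array([0.47, 0.45, 0.44]),
        "CDKN1A": np.array([0.38, 0.40, 0.42]),
        "PDE7B": np.array([0.35, 0.33, 0.36]),
    }
    t2d = {
        "MEG3": spread(0.61, 19),
        "INS": spread(0.46, 4, 0.03),
        "IRS1": np.array([0.37, 0.43, 0.42]),
        "CDKN1A": np.array([0.38, 0.30, 0.32]),
        "PDE7B": np.array([0.35, 0.33, 0.36]),
    }
    kwargs = dict(
        conversion_rate=conversion_rate,
        error_rate=error_rate,
        read_length=read_length,
        n_pairs=n_pairs,
    )
    return {
        "ND": SimProfile(methylation=nd, **kwargs),
        "T2D": SimProfile(methylation=t2d, **kwargs),
    }
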