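# Methods

## Assay model

A targeted bisulfite panel is a set of short PCR amplicons designed
against sodium-bisulfite-converted genomic DNA. `bisamp` represents one
amplicon as a `TargetAssay`: a genomic interval (1-based closed, as
assay tables print them; all internal arithmetic is 0-based half-open,
converted only at the BED boundary), the primer-to-primer top-strand
region sequence, the CpG offsets within it, and the primer footprints —
the flanks synthesized from primer oligos rather than template, which
carry no methylation information.

Library-length prediction reflects the two-round PCR structure: the
first round prepends a 33-nt left and a 34-nt right partial-adapter
overhang to the locus-specific primers; the second anneals to those
overhangs and extends them 5′ by 25 nt (left) and 24 nt plus a 6-nt
sample index (right). A region of length L therefore yields an
L + 122 bp library fragment with the default `AdapterScheme`. The
second-round primer structure is modeled as single-index barcoding with
those extension lengths; this is the unique single-index layout
consistent with the +122 arithmetic observed across the five-amplicon
reference panel, and the index length is a parameter for other
chemistries. One documented quirk of that panel is that the printed
MEG3 coordinates span 306 bp while the region itself is 298 bp; the
region length is treated as authoritative throughout, and intervals are
stored as printed without cross-validation against sequence length.

Primers are stored in bisulfite space — as designed against the
converted, fully unmethylated template. `validate_assay` is report-only
and flags CpGs inside primer footprints (their methylation is
unreadable), primer bases that disagree character-wise with the
converted template, and the predicted library length. No
melting-temperature or secondary-structure modeling is attempted;
thermodynamic design belongs to dedicated assay-design software.

## Read simulation

The simulator draws whole converted molecules per amplicon. At a CpG
with true methylation level m and conversion rate λ, the cytosine
survives as C with probability m + (1 − m)(1 − λ): methylation protects
it, and conversion failure spares it even when unmethylated. Every
non-CpG cytosine survives only on conversion failure (probability
1 − λ). Methylation states are drawn independently per CpG per molecule;
real epialleles show within-molecule correlation, but only marginal
per-CpG fractions are quantified downstream, so the marginal model is
sufficient for what the pipeline measures (a correlation knob is a
possible extension, deliberately not a default).

R1 is the first `read_length` bases of the molecule, R2 the reverse
complement of the last `read_length` bases (truncated to the molecule
for short amplicons); substitution errors are applied per base at rate
ε, uniformly over the three other bases, and qualities are a constant
placeholder since no quality-dependent processing exists downstream.
PCR amplification bias is not simulated — per-assay depth is set
directly, and the empirical balance is what the QC report measures on
real data.

Defaults are chosen to emulate the reference study design: five
amplicons of 153–298 bp, ten samples in two groups of five, 150 bp
paired-end reads, and 200,000 pairs per amplicon per sample. Tests and
the acceptance script use 300–5,000 pairs per amplicon-sample: at the
binomial precision involved (SE ≈ 0.007 at 5,000 calls) the smaller
depth already makes sampling noise negligible next to the simulated
effects, which is the property the study-scale depth buys. λ defaults
to 0.995 — a realistic figure for commercial kits; the reference study
does not report one — and ε to 0.001. Every generator is seeded from
`(seed, sample_ordinal)`, so studies regenerate byte-identically.

The demo panel (`islet_demo_panel`) mirrors the published islet panel's
printed coordinates, region lengths, and per-amplicon CpG counts
(MEG3 19, INS 4, IRS1 3, CDKN1A 3, PDE7B 3), and carries the published
MEG3 primer pair verbatim. Its region sequences are **synthetic** —
deterministically generated with evenly spaced CpGs and C-free primer
footprints — because no reference genome ships with the package.
Consequences: tests and simulations exercise the real panel geometry
exactly, but base-level results do not correspond to real hg19
positions, and passing tests say nothing about primer specificity or
alignment against genomic repeats. The default group profiles
(`islet_study_profiles`) place region-mean methylation at 0.43 vs 0.61
(MEG3), 0.24 vs 0.46 (INS), a 0.10 drop at the first IRS1 CpG and the
second/third CDKN1A CpGs, and equal levels at PDE7B, emulating the
reference study's reported group differences within the ~20–65 %
per-CpG range.

## Alignment

Reads are matched in a reduced three-letter alphabet: C collapsed to T
on both read and reference, so a methylated (C) or unmethylated (T)
base aligns equally well and methylation state cannot bias placement.
Because amplicon reads have fixed endpoints, alignment is an exhaustive
ungapped sliding-offset scan over the short reference — exact by
construction and verified against brute force in the tests. Ties go to
the smallest offset. Indels are not modeled; an indel-tolerant banded
mode would be an extension, not a default, since the assay produces
fixed-structure fragments.

Pair-to-amplicon assignment compares R1 against each amplicon's
converted prefix and the reverse-complemented R2 against its suffix,
and accepts the minimum-mismatch amplicon only if it meets the mismatch
ceiling (10 % of aligned length) and beats the runner-up by at least 5
mismatches; ties and near-ties are binned as unassigned rather than
guessed. Both thresholds are configuration, logged with every run; they
are loose for ε ≤ 1 % reads and panels as dissimilar as real loci.
There is no PCR-duplicate removal: in amplicon sequencing every read is
a duplicate by construction, and quantification is depth-based.

The pipeline's batch path performs the same computations vectorized
over NumPy byte matrices (grouped by read length); the suite asserts
cell-for-cell equality between the batch path and the scalar
operations.

## Methylation calling

The observed original base at each covered, unmasked CpG becomes a
call: C methylated, T unmethylated, anything else ambiguous. Where the
mates of a pair overlap, the first read's call is kept and the second
read's discarded — first-read precedence, applied literally, so each
pair contributes at most one call per CpG. The reported fraction is
count_C / (count_C + count_T): ambiguous bases are excluded from the
denominator because a non-C/T base carries no methylation information
(the counts remain in the output for audit). Primer-footprint CpGs are
masked by default (their bases are primer oligo, not template); a flag
disables masking for assays where the footprint is known to be
template-derived. There is no minimum-coverage threshold by default —
at amplicon depths coverage is never limiting — but `--min-coverage`
undefined-marks shallow cells for low-depth reuse, keeping counts.

Conversion efficiency is estimated per sample as the T fraction among
{C, T} observations at non-CpG cytosine reference positions outside
footprints; with the simulator's bias law, the expected observed CpG
fraction is m + (1 − m)(1 − λ), which the tests verify.

## Statistics

Per-CpG group comparisons are two-tailed Student pooled-variance
t-tests across per-sample fractions (df = n₁ + n₂ − 2), with one
additional test per amplicon on the per-sample region averages
(unweighted mean over defined CpGs — averaging per sample first is the
only reading consistent with n = 5 degrees of freedom). SEM is the
sample SD over √n. Significance is p < α (default 0.05) with no
multiple-testing correction by default, matching the per-CpG reporting
convention of the assays this reproduces; Benjamini–Hochberg is
available (`correction="bh"`, CpG and region rows adjusted as separate
families), as is Welch's test. Degenerate inputs never crash: two
constant equal groups give t = 0, p = 1; two constant unequal groups
give p = 0 with a `degenerate` flag, since the certainty is an artifact
of zero sampled variance. The unit of replication is always the
biological sample; read depth only sets per-sample fraction precision.

Library-balance QC reports reads per sample, per amplicon-sample cell,
and the expected per-cell depth (total assigned / (samples × assays)),
the quantity used to judge pooling balance.

## Numerical and interface choices

* Mismatch counting, placement, and calling are integer/byte exact; the
  only floating-point quantities are fractions and test statistics.
* Undefined values (zero denominators, all-NaN region averages) are NaN
  throughout — never exceptions, never zeros.
* Output tables are plain TSV; fractions round-trip through files
  losslessly enough that reruns compare equal (`pandas` default float
  formatting).
* The t-test p-value is computed by `scipy.stats`; the test suite keeps
  an independent textbook implementation of the pooled formula as an
  oracle at 1e-10.
* FASTQ parsing uses Biopython's `FastqGeneralIterator`; pair streams
  fail loudly, naming the pair index, on count mismatches.

## Scales used by the shipped checks

The test suite and `scripts/acceptance.py` simulate at 300–5,000 pairs
per amplicon-sample and calibrate the null on 2,000 CpGs at 5,000
informative calls each — sizes at which every asserted tolerance is ≥ 4
binomial standard errors wide. The null calibration drives the
comparison stage on binomially sampled per-sample fractions directly:
read depth enters the test statistic only through fraction precision,
and the read-level path is exercised by the paired two-group study run
in the same scripts.

## Known limitations

* Synthetic demo-panel sequences: no statement about real-genome primer
  specificity, repeats, or SNP overlap.
* No indel handling, no gapped alignment, no mapping-quality model.
* No CHH/CHG context calling, no epiallele/haplotype reconstruction,
  no SNP-aware calling.
* The statistics assume approximately normal per-sample fractions
  (excellent at amplicon depths); no beta-binomial dispersion modeling
  and no covariate adjustment.
* Index demultiplexing is provided as an operation on (index, pair)
  streams; the primary input mode is pre-demultiplexed per-sample FASTQ
  pairs, which is how sequencers deliver targeted runs.
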