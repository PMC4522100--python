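"""Methylation calling: state mapping, overlap rule, fractions, QC."""

import math

import numpy as np
import pytest

import bisamp as B
from bisamp.align import AmpliconAlignment, align_to_amplicon, mask_primer_positions
from bisamp.assay import GenomicInterval, TargetAssay, bisulfite_convert
from bisamp.methcall import (
    AMBIGUOUS,
    METHYLATED,
    UNMETHYLATED,
    CpGCall,
    MethylationAccumulator,
    call_read_cpgs,
    conversion_efficiency,
    coverage_filter,
    fraction_methylated,
    merge_pair_calls,
)

from conftest import perfect_reads


@pytest.fixture()
def tiny_assay():
    # CpGs at offsets 2 and 8; non-CpG Cs at 5 and 12; footprints empty
    region = "TACGTCTACGTTCTTTAAAG"
    iv = GenomicInterval("chr1", 101, 120)
    return TargetAssay(
        "tiny", iv, region, "TA", "CT", primer_footprints=((0, 0),)
    )


def _aln(assay, observed, offset=0, mate="R1", masked=()):
    return AmpliconAlignment(
        assay_name=assay.name, mate=mate, offset=offset,
        n_mismatch=0, observed=observed, masked=frozenset(masked),
    )


class TestCallReadCpgs:
    def test_c_t_and_error_states(self, tiny_assay):
        # offsets 2 and 8: C -> methylated, A -> ambiguous
        observed = "TACGTTTAAGTTTTTTAAAG"
        calls = call_read_cpgs(_aln(tiny_assay, observed), tiny_assay)
        assert calls == [
            CpGCall("tiny", 2, METHYLATED),
            CpGCall("tiny", 8, AMBIGUOUS),
        ]

    def test_t_maps_to_unmethylated(self, tiny_assay):
        observed = bisulfite_convert(tiny_assay.region_seq, protect_cpg=False)
        calls = call_read_cpgs(_aln(tiny_assay, observed), tiny_assay)
        assert [c.state for c in calls] == [UNMETHYLATED, UNMETHYLATED]

    def test_masked_cpg_is_omitted(self, tiny_assay):
        observed = tiny_assay.region_seq
        calls = call_read_cpgs(_aln(tiny_assay, observed, masked={2}), tiny_assay)
        assert [c.cpg_offset for c in calls] == [8]

    def test_uncovered_cpg_is_omitted(self, tiny_assay):
        calls = call_read_cpgs(_aln(tiny_assay, "CGTT", offset=7), tiny_assay)
        assert [c.cpg_offset for c in calls] == [8]


class TestMergePairCalls:
    def test_r1_precedence_on_conflict(self):
        r1 = [CpGCall("a", 10, METHYLATED)]
        r2 = [CpGCall("a", 10, UNMETHYLATED)]
        assert merge_pair_calls(r1, r2) == [CpGCall("a", 10, METHYLATED)]

    def test_disjoint_union(self):
        r1 = [CpGCall("a", 10, METHYLATED)]
        r2 = [CpGCall("a", 50, UNMETHYLATED)]
        assert merge_pair_calls(r1, r2) == [
            CpGCall("a", 10, METHYLATED),
            CpGCall("a", 50, UNMETHYLATED),
        ]

    def test_empty_r1_keeps_r2(self):
        r2 = [CpGCall("a", 50, METHYLATED)]
        assert merge_pair_calls([], r2) == r2

    def test_mixed_assays_rejected(self):
        with pytest.raises(ValueError):
            merge_pair_calls(
                [CpGCall("a", 1, METHYLATED)], [CpGCall("b", 2, METHYLATED)]
            )

    def test_no_offset_counted_twice_on_real_overlap(self, meg3):
        # 298 bp region with 150 bp mates: 2-base molecule overlap
        r1, r2, _ = perfect_reads(meg3, methylated=True)
        a1 = align_to_amplicon(r1, meg3, "R1")
        a2 = align_to_amplicon(r2, meg3, "R2")
        merged = merge_pair_calls(
            call_read_cpgs(a1, meg3), call_read_cpgs(a2, meg3)
        )
        offsets = [c.cpg_offset for c in merged]
        assert len(offsets) == len(set(offsets))
        assert set(offsets) == set(meg3.cpg_offsets)


class TestFraction:
    @pytest.mark.parametrize("c,t,expected", [(3, 1, 0.75), (0, 10, 0.0), (5, 0, 1.0)])
    def test_fraction_examples(self, c, t, expected):
        assert fraction_methylated(c, t) == expected

    def test_zero_denominator_is_nan_not_crash(self):
        assert math.isnan(fraction_methylated(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fraction_methylated(-1, 2)


class TestAccumulator:
    def test_conservation_of_calls(self):
        acc = MethylationAccumulator()
        states = [METHYLATED] * 3 + [UNMETHYLATED] * 2 + [AMBIGUOUS]
        for s in states:
            acc.add_calls("s1", [CpGCall("a", 4, s)])
        m = acc.to_matrix()
        row = m.iloc[0]
        assert (row["count_c"], row["count_t"], row["count_ambiguous"]) == (3, 2, 1)
        assert row["count_c"] + row["count_t"] + row["count_ambiguous"] == len(states)
        assert row["fraction"] == pytest.approx(0.6)

    def test_zero_coverage_cell_is_nan(self):
        acc = MethylationAccumulator()
        acc.ensure_cell("s1", "a", 0)
        m = acc.to_matrix()
        assert math.isnan(m.iloc[0]["fraction"])


class TestConversionEfficiency:
    def test_perfect_conversion_limit(self, tiny_assay):
        observed = bisulfite_convert(tiny_assay.region_seq, protect_cpg=True)
        eff = conversion_efficiency([_aln(tiny_assay, observed)], tiny_assay)
        assert eff == 1.0

    def test_no_informative_positions_is_nan(self):
        iv = GenomicInterval("chr1", 1, 8)
        assay = TargetAssay("x", iv, "TTAAGGTT", "TT", "AA", primer_footprints=((0, 0),))
        assert assay.non_cpg_c_offsets() == []
        aln = _aln(assay, "TTAAGGTT")
        assert math.isnan(conversion_efficiency([aln], assay))

    def test_incomplete_conversion_estimated_within_binomial_error(self, pde7b):
        lam, n = 0.98, 4000
        rng = np.random.default_rng(77)
        profile = B.flat_profile([pde7b], 0.5, conversion_rate=lam, error_rate=0.0,
                                 n_pairs=n)
        sim = B.simulate_sample_reads([pde7b], profile, "s", rng)
        alns = [
            mask_primer_positions(align_to_amplicon(s, pde7b, "R1"), pde7b)
            for _, s, _ in sim.r1_records[:1000]
        ]
        est = conversion_efficiency(alns, pde7b)
        n_obs = 1000 * len(pde7b.non_cpg_c_offsets())
        se = math.sqrt(lam * (1 - lam) / n_obs)
        assert abs(est - lam) < 4 * se


class TestCoverageFilter:
    def test_zero_threshold_is_identity(self):
        acc = MethylationAccumulator()
        acc.add_counts("s", "a", 0, 40, 60)
        m = acc.to_matrix()
        out = coverage_filter(m, 0)
        assert out.equals(m)

    def test_low_coverage_cell_marked_undefined_counts_kept(self):
        acc = MethylationAccumulator()
        acc.add_counts("s", "a", 0, 40, 59)  # 99 informative calls
        acc.add_counts("s", "a", 5, 60, 60)
        out = coverage_filter(acc.to_matrix(), 100)
        assert math.isnan(out.iloc[0]["fraction"])
        assert out.iloc[0]["count_c"] == 40
        assert out.iloc[1]["fraction"] == pytest.approx(0.5)


class TestBiasLaw:
    @pytest.mark.parametrize("m", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_parameter_recovery_grid(self, pde7b, m):
        # with lambda=1 and no errors, fraction estimates m to binomial error
        n = 10_000
        rng = np.random.default_rng(int(m * 100) + 1)
        profile = B.flat_profile([pde7b], m, conversion_rate=1.0, error_rate=0.0,
                                 n_pairs=n)
        acc = MethylationAccumulator()
        from bisamp.pipeline import process_sample_pairs
        sim = B.simulate_sample_reads([pde7b], profile, "s", rng)
        pairs = zip(sim.r1_records, sim.r2_records)
        process_sample_pairs("s", pairs, [pde7b], acc)
        matrix = acc.to_matrix()
        tol = 4 * math.sqrt(max(m * (1 - m), 1e-12) / n) + 1e-9
        for _, row in matrix.iterrows():
            assert abs(row["fraction"] - m) <= tol

    def test_incomplete_conversion_bias_law(self, pde7b):
        # expected fraction = m + (1-m)(1-lambda)
        m, lam, n = 0.4, 0.97, 10_000
        rng = np.random.default_rng(8)
        profile = B.flat_profile([pde7b], m, conversion_rate=lam, error_rate=0.0,
                                 n_pairs=n)
        acc = MethylationAccumulator()
        from bisamp.pipeline import process_sample_pairs
        sim = B.simulate_sample_reads([pde7b], profile, "s", rng)
        process_sample_pairs("s", zip(sim.r1_records, sim.r2_records), [pde7b], acc)
        expected = m + (1 - m) * (1 - lam)
        se = math.sqrt(expected * (1 - expected) / n)
        for _, row in acc.to_matrix().iterrows():
            assert abs(row["fraction"] - expected) < 4 * se
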