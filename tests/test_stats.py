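"""Group statistics: pooled t-test, SEM reporting, allocation QC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import stdtr

from bisamp.methcall import MethylationAccumulator
from bisamp.stats import (
    compare_groups,
    read_allocation_report,
    region_average,
    two_sample_ttest,
)


def textbook_pooled_t(a, b):
    """Independent pooled-variance t-test from the textbook formula."""
    a, b = list(a), list(b)
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * stdtr(df, -abs(t))
    return t, df, p


class TestTwoSampleTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        a = [0.1, 0.2, 0.3]
        res = two_sample_ttest(a, a)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        a = [0.40, 0.42, 0.44, 0.43, 0.41]
        b = [0.60, 0.62, 0.58, 0.61, 0.59]
        res = two_sample_ttest(a, b)
        assert res.t == pytest.approx(-18.0, abs=1e-10)
        assert res.df == 8
        assert res.p == pytest.approx(9.308830966371836e-08, rel=1e-9)

    def test_antisymmetry(self):
        a = [0.1, 0.15, 0.2]
        b = [0.3, 0.32, 0.41]
        fwd = two_sample_ttest(a, b)
        rev = two_sample_ttest(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_matches_textbook_formula_on_random_inputs(self):
        rng = np.random.default_rng(19)
        for _ in range(1000):
            na, nb = rng.integers(2, 9, size=2)
            a = rng.random(na)
            b = rng.random(nb)
            t, df, p = textbook_pooled_t(a, b)
            res = two_sample_ttest(a, b)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.df == df
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_constant_equal_groups(self):
        res = two_sample_ttest([0.5, 0.5], [0.5, 0.5])
        assert (res.t, res.p, res.degenerate) == (0.0, 1.0, False)

    def test_constant_unequal_groups_flagged_degenerate(self):
        res = two_sample_ttest([0.5, 0.5], [0.6, 0.6])
        assert res.p == 0.0 and res.degenerate
        assert res.t == -math.inf

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([0.5], [0.4, 0.6])

    def test_welch_handles_unequal_variances(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.001, 5)
        b = rng.normal(0, 0.5, 5)
        res = two_sample_ttest(a, b, welch=True)
        assert res.df < 8  # Welch df shrinks under variance imbalance


class TestRegionAverage:
    def _matrix(self, cells):
        rows = [
            ("s", "a", o, 0, 0, 0, f) for o, f in cells
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "assay", "cpg_offset", "count_c", "count_t",
                     "count_ambiguous", "fraction"],
        )

    def test_unweighted_mean(self):
        m = self._matrix([(0, 0.4), (5, 0.6)])
        assert region_average(m, "a", "s") == pytest.approx(0.5)

    def test_single_cpg(self):
        m = self._matrix([(0, 0.43)])
        assert region_average(m, "a", "s") == pytest.approx(0.43)

    def test_undefined_cells_excluded_and_all_nan_is_nan(self):
        m = self._matrix([(0, 0.4), (5, math.nan)])
        assert region_average(m, "a", "s") == pytest.approx(0.4)
        assert math.isnan(region_average(self._matrix([(0, math.nan)]), "a", "s"))


class TestAllocationReport:
    def test_expected_reads_per_amplicon_sample(self):
        rows = [
            (f"s{i}", f"a{j}", 200_000) for i in range(10) for j in range(5)
        ]
        report = read_allocation_report(
            pd.DataFrame(rows, columns=["sample", "assay", "reads"])
        )
        assert report.total_assigned == 10_000_000
        assert report.expected_per_cell == pytest.approx(200_000)

    def test_single_cell(self):
        report = read_allocation_report(
            pd.DataFrame([("s", "a", 7)], columns=["sample", "assay", "reads"])
        )
        assert report.per_sample.iloc[0]["fraction_of_run"] == pytest.approx(1.0)
        assert report.per_cell.iloc[0]["reads"] == 7

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"s{i}", f"a{j}", int(rng.integers(1, 10_000)))
            for i in range(8) for j in range(5)
        ]
        report = read_allocation_report(
            pd.DataFrame(rows, columns=["sample", "assay", "reads"])
        )
        assert report.per_sample["fraction_of_run"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_reads_empty_report(self):
        report = read_allocation_report(
            pd.DataFrame([("s", "a", 0)], columns=["sample", "assay", "reads"])
        )
        assert report.empty and report.expected_per_cell == 0.0


def _study_matrix(rng, group_means, n_per_group=5, depth=5000, n_cpgs=4):
    """Binomial per-sample fractions for a two-group synthetic locus."""
    acc = MethylationAccumulator()
    sheet_rows = []
    for g, mean in group_means.items():
        for i in range(n_per_group):
            sample = f"{g}_{i}"
            sheet_rows.append((sample, g))
            for o in range(n_cpgs):
                c = rng.binomial(depth, mean)
                acc.add_counts(sample, "locus", o * 3, c, depth - c)
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "group"])
    return acc.to_matrix(), sheet


class TestCompareGroups:
    def test_large_effect_all_cpgs_significant(self):
        rng = np.random.default_rng(21)
        matrix, sheet = _study_matrix(rng, {"A": 0.24, "B": 0.46})
        comp = compare_groups(matrix, sheet)
        cpg = comp.table[comp.table["kind"] == "cpg"]
        assert len(cpg) == 4
        assert cpg["significant"].all()
        assert (cpg["p"] < 0.05).all()
        region = comp.table[comp.table["kind"] == "region"]
        assert len(region) == 1
        assert region.iloc[0]["mean_A"] == pytest.approx(0.24, abs=0.02)
        assert region.iloc[0]["mean_B"] == pytest.approx(0.46, abs=0.02)

    def test_sem_is_sd_over_sqrt_n(self):
        rng = np.random.default_rng(3)
        matrix, sheet = _study_matrix(rng, {"A": 0.4, "B": 0.4}, n_per_group=5)
        comp = compare_groups(matrix, sheet)
        row = comp.table[comp.table["kind"] == "cpg"].iloc[0]
        fracs = matrix[matrix["cpg_offset"] == 0].merge(
            sheet, left_on="sample", right_on="sample_id"
        )
        a = fracs.loc[fracs["group"] == "A", "fraction"].to_numpy()
        assert row["sem_A"] == pytest.approx(np.std(a, ddof=1) / math.sqrt(5))

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        flags = []
        for _ in range(250):  # 250 loci x 4 CpGs = 1000 null tests
            matrix, sheet = _study_matrix(rng, {"A": 0.4, "B": 0.4})
            comp = compare_groups(matrix, sheet)
            flags.extend(comp.table.loc[comp.table["kind"] == "cpg", "significant"])
        rate = np.mean(flags)
        assert 0.03 <= rate <= 0.07

    def test_degenerate_zero_variance_path(self):
        acc = MethylationAccumulator()
        for g, frac in (("A", 0.2), ("B", 0.8)):
            for i in range(2):
                acc.add_counts(f"{g}{i}", "x", 0, int(frac * 10), 10 - int(frac * 10))
        sheet = pd.DataFrame(
            [("A0", "A"), ("A1", "A"), ("B0", "B"), ("B1", "B")],
            columns=["sample_id", "group"],
        )
        comp = compare_groups(acc.to_matrix(), sheet)
        row = comp.table[comp.table["kind"] == "cpg"].iloc[0]
        assert row["degenerate"] and row["p"] == 0.0 and row["significant"]

    def test_requires_exactly_two_groups(self):
        rng = np.random.default_rng(0)
        matrix, sheet = _study_matrix(rng, {"A": 0.3, "B": 0.4})
        sheet3 = pd.concat(
            [sheet, pd.DataFrame([("c1", "C")], columns=sheet.columns)]
        )
        with pytest.raises(ValueError):
            compare_groups(matrix, sheet3)

    def test_group_with_one_sample_rejected(self):
        rng = np.random.default_rng(0)
        matrix, sheet = _study_matrix(rng, {"A": 0.3, "B": 0.4}, n_per_group=1)
        with pytest.raises(ValueError):
            compare_groups(matrix, sheet)

    def test_bh_correction_adds_adjusted_column(self):
        rng = np.random.default_rng(13)
        matrix, sheet = _study_matrix(rng, {"A": 0.24, "B": 0.46})
        comp = compare_groups(matrix, sheet, correction="bh")
        assert "p_adj" in comp.table.columns
        cpg = comp.table[comp.table["kind"] == "cpg"]
        assert (cpg["p_adj"] >= cpg["p"] - 1e-15).all()
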