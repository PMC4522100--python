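"""Library-balance QC and two-group differential methylation statistics.

The unit of replication is the biological sample: per-CpG methylation
fractions are computed per sample first, and group comparisons are
two-tailed t-tests across those per-sample fractions (n per group,
default design 5 vs 5). Read depth only sets the precision of each
per-sample fraction. Results are reported as group mean +/- SEM with a
significance flag at alpha (default 0.05); no multiple-testing
correction is applied by default, with Benjamini-Hochberg available as
an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AllocationReport",
    "GroupComparison",
    "two_sample_ttest",
    "region_average",
    "read_allocation_report",
    "compare_groups",
]


class TTestResult(NamedTuple):
    """Two-sample t-test outcome.

    ``degenerate`` flags the pathological case of two constant, unequal
    groups (zero pooled variance): the difference is then certain but
    the t statistic is unbounded, reported as +/-inf with p = 0.
    """

    t: float
    df: int
    p: float
    degenerate: bool = False


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-tailed two-sample t-test on per-sample methylation fractions.

    Student's pooled-variance test by default (df = n_a + n_b - 2);
    Welch's unequal-variance test with ``welch=True``. Degenerate
    zero-variance inputs never raise: two constant equal groups give
    t = 0, p = 1; two constant unequal groups give p = 0 with the
    ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, degenerate=False)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(sign * math.inf, df, 0.0, degenerate=True)
    with warnings.catch_warnings():
        # near-identical groups trip scipy's precision warning; the truly
        # degenerate zero-variance cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else df
    return TTestResult(float(res.statistic), df, float(res.pvalue), degenerate=False)


def region_average(matrix: pd.DataFrame, assay: str, sample: str) -> float:
    """Unweighted mean of defined per-CpG fractions for one sample/assay.

    NaN (undefined-marked) when no CpG cell is defined.
    """
    sub = matrix[(matrix["assay"] == assay) & (matrix["sample"] == sample)]
    fractions = sub["fraction"].dropna()
    if fractions.empty:
        return math.nan
    return float(fractions.mean())


@dataclass
class AllocationReport:
    """Reads-per-amplicon-per-sample balance of a sequencing run.

    ``per_sample`` has columns (sample, reads, fraction_of_run);
    ``per_cell`` has one row per sample x assay. ``expected_per_cell``
    is total assigned reads / (n_assays * n_samples) — the depth every
    cell would get under perfect balance.
    """

    per_sample: pd.DataFrame
    per_cell: pd.DataFrame
    per_assay_mean: pd.DataFrame
    total_assigned: int
    expected_per_cell: float

    @property
    def empty(self) -> bool:
        return self.total_assigned == 0


def read_allocation_report(assignment_counts: pd.DataFrame) -> AllocationReport:
    """Summarize library balance from per-sample x assay read counts.

    ``assignment_counts`` is long-format with columns (sample, assay,
    reads). Zero assigned reads yields an empty report rather than an
    error.
    """
    required = {"sample", "assay", "reads"}
    if not required.issubset(assignment_counts.columns):
        raise ValueError(f"assignment_counts needs columns {sorted(required)}")
    counts = assignment_counts.copy()
    if (counts["reads"] < 0).any():
        raise ValueError("read counts must be non-negative")
    total = int(counts["reads"].sum())
    per_sample = (
        counts.groupby("sample", as_index=False)["reads"].sum().sort_values("sample")
    )
    per_sample["fraction_of_run"] = (
        per_sample["reads"] / total if total else 0.0
    )
    per_assay_mean = (
        counts.groupby("assay", as_index=False)["reads"].mean().sort_values("assay")
    ).rename(columns={"reads": "mean_reads"})
    n_samples = counts["sample"].nunique()
    n_assays = counts["assay"].nunique()
    expected = total / (n_samples * n_assays) if total else 0.0
    return AllocationReport(
        per_sample=per_sample.reset_index(drop=True),
        per_cell=counts.reset_index(drop=True),
        per_assay_mean=per_assay_mean.reset_index(drop=True),
        total_assigned=total,
        expected_per_cell=expected,
    )


@dataclass
class GroupComparison:
    """Per-CpG and per-region two-group differential methylation table.

    ``table`` holds one row per (assay, CpG) plus one region-average
    row per assay (``cpg_offset`` is NaN, ``kind`` is ``"region"``),
    with group means, SEMs, t, df, two-tailed p, and the significance
    flag at ``alpha``.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    alpha: float


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


def compare_groups(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    alpha: float = 0.05,
    correction: str | None = None,
    welch: bool = False,
) -> GroupComparison:
    """Two-group differential methylation per CpG and per region.

    ``sample_sheet`` needs columns (sample_id, group) with exactly two
    groups of >= 2 samples each. For every assay/CpG the per-sample
    fractions are compared across groups with :func:`two_sample_ttest`;
    one additional test per assay compares the per-sample region
    averages. Group order follows first appearance in the sheet.

    ``correction="bh"`` adds a Benjamini-Hochberg ``p_adj`` column
    (CpG rows and region rows adjusted as separate families); the
    ``significant`` flag is then based on ``p_adj``.
    """
    groups = list(dict.fromkeys(sample_sheet["group"]))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    ga, gb = groups
    members = {
        g: list(sample_sheet.loc[sample_sheet["group"] == g, "sample_id"])
        for g in groups
    }
    for g, m in members.items():
        if len(m) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    frac = matrix.pivot_table(
        index=["assay", "cpg_offset"], columns="sample", values="fraction"
    )
    rows = []

    def _test_row(assay: str, offset: float, kind: str, series: pd.Series) -> None:
        va = series.reindex(members[ga]).dropna().to_numpy()
        vb = series.reindex(members[gb]).dropna().to_numpy()
        if len(va) < 2 or len(vb) < 2:
            rows.append(
                (assay, offset, kind, np.nan, np.nan, np.nan, np.nan,
                 np.nan, np.nan, np.nan, False, False)
            )
            return
        res = two_sample_ttest(va, vb, welch=welch)
        rows.append(
            (
                assay, offset, kind,
                float(va.mean()), _sem(va), float(vb.mean()), _sem(vb),
                res.t, res.df, res.p, bool(res.p < alpha), res.degenerate,
            )
        )

    for (assay, offset), series in frac.iterrows():
        _test_row(assay, float(offset), "cpg", series)

    for assay in frac.index.get_level_values("assay").unique():
        samples = frac.columns
        region = pd.Series(
            {s: region_average(matrix, assay, s) for s in samples}
        )
        _test_row(assay, math.nan, "region", region)

    table = pd.DataFrame(
        rows,
        columns=[
            "assay", "cpg_offset", "kind",
            f"mean_{ga}", f"sem_{ga}", f"mean_{gb}", f"sem_{gb}",
            "t", "df", "p", "significant", "degenerate",
        ],
    ).sort_values(["assay", "kind", "cpg_offset"], na_position="last").reset_index(drop=True)

    if correction is not None:
        if correction.lower() != "bh":
            raise ValueError(f"unknown correction {correction!r}")
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = np.nan
        for kind in ("cpg", "region"):
            mask = (table["kind"] == kind) & table["p"].notna()
            if mask.any():
                _, p_adj, _, _ = multipletests(
                    table.loc[mask, "p"], alpha=alpha, method="fdr_bh"
                )
                table.loc[mask, "p_adj"] = p_adj
        table["significant"] = table["p_adj"] < alpha

    return GroupComparison(table=table, group_a=ga, group_b=gb, alpha=alpha)
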