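"""Per-sample summaries, group averages and between-group hypothesis tests.

The summary mirrors the cohort-table layout used for the study samples:
cell counts, distinct-sequence counts, the proportion of potentially
functional T cells (those that can pair at least one alpha(F)+beta(F)),
and — among functional cells — the single/multiple TCR split.  Group
averages are *unweighted arithmetic means of per-sample percentages*, not
pooled-cell ratios: that is how the published Average rows are computed,
and small samples deliberately count as much as large ones.

Percentages are carried at full precision and formatted to 3 decimals with
half-up rounding when reported, matching the published table strings.

Between-group tests follow a standard dispatch: two normal groups ->
two-tailed t test; three or more normal, homoscedastic groups -> one-way
ANOVA; otherwise Mann-Whitney (2 groups) or Kruskal-Wallis (>=3).
Normality is screened per group by Shapiro-Wilk at alpha=0.05 and variance
homogeneity by Levene at alpha=0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from scipy import stats

from .chain_model import CellProfile, unique_sequence_count
from .cell_patterns import (
    GROUPS,
    PATTERN_NAMES,
    assign_pattern,
    chain_count_group,
    classify_tcr_status,
)


def round3(value: float) -> float:
    """Half-up rounding to 3 decimals (spreadsheet-style, not banker's)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.001"),
                                                      rounding=ROUND_HALF_UP))


@dataclass
class SampleSummary:
    sample_id: str
    n_cells: int
    n_functional: int
    pct_functional: float
    pct_abnormal: float
    pct_single: float | None      # None when the sample has no functional cells
    pct_multiple: float | None
    n_unique_sequences: int | None = None
    pattern_freqs: dict[int, float] = field(default_factory=dict)
    group_freqs: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_percentages(
        cls,
        sample_id: str,
        pct_functional: float,
        pct_single: float | None = None,
        pct_multiple: float | None = None,
        n_cells: int = 0,
        n_functional: int = 0,
        n_unique_sequences: int | None = None,
    ) -> "SampleSummary":
        """Build a summary from precomputed percentages (summaries-only mode)."""
        return cls(
            sample_id=sample_id,
            n_cells=n_cells,
            n_functional=n_functional,
            pct_functional=pct_functional,
            pct_abnormal=100.0 - pct_functional,
            pct_single=pct_single,
            pct_multiple=pct_multiple,
            n_unique_sequences=n_unique_sequences,
        )


@dataclass
class GroupSummary:
    group_id: str
    sample_ids: list[str]
    mean_pct_functional: float
    mean_pct_single: float | None
    mean_pct_multiple: float | None


@dataclass
class TestResult:
    test_name: str        # t_test_two_tailed / anova_one_way / mann_whitney / kruskal_wallis
    statistic: float
    p_value: float
    significance_label: str   # ns / * / **
    screens: dict[str, object] = field(default_factory=dict)


def significance_label(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_sample(profiles: list[CellProfile], sample_id: str) -> SampleSummary:
    """Summarize one sample's classified cells.

    ``pct_single``/``pct_multiple`` are percentages *of functional cells*
    (they sum to 100); ``pct_functional``/``pct_abnormal`` are percentages
    of all classified cells.  With zero functional cells the single/multiple
    split is undefined and reported as ``None``, never as 0.
    """
    if not profiles:
        raise ValueError("summarize_sample requires at least one cell profile")
    n_cells = len(profiles)
    statuses = [classify_tcr_status(p) for p in profiles]
    n_single = statuses.count("single")
    n_multiple = statuses.count("multiple")
    n_functional = n_single + n_multiple
    n_abnormal = statuses.count("abnormal")

    pattern_counts = {code: 0 for code in PATTERN_NAMES}
    for p in profiles:
        pattern_counts[assign_pattern(p).code] += 1
    group_counts = {g: 0 for g in GROUPS}
    for p in profiles:
        group_counts[chain_count_group(p)] += 1

    return SampleSummary(
        sample_id=sample_id,
        n_cells=n_cells,
        n_functional=n_functional,
        n_unique_sequences=unique_sequence_count(profiles),
        pct_functional=100.0 * n_functional / n_cells,
        pct_abnormal=100.0 * n_abnormal / n_cells,
        pct_single=100.0 * n_single / n_functional if n_functional else None,
        pct_multiple=100.0 * n_multiple / n_functional if n_functional else None,
        pattern_freqs={c: k / n_cells for c, k in pattern_counts.items()},
        group_freqs={g: k / n_cells for g, k in group_counts.items()},
    )


def aggregate_group(summaries: list[SampleSummary], group_id: str) -> GroupSummary:
    """Unweighted arithmetic means of member-sample percentages.

    Samples lacking a single/multiple split (no functional cells) are
    excluded from those two means only.
    """
    if not summaries:
        raise ValueError(f"group {group_id!r} has no member samples")
    mean = lambda xs: sum(xs) / len(xs)
    singles = [s.pct_single for s in summaries if s.pct_single is not None]
    multiples = [s.pct_multiple for s in summaries if s.pct_multiple is not None]
    return GroupSummary(
        group_id=group_id,
        sample_ids=[s.sample_id for s in summaries],
        mean_pct_functional=mean([s.pct_functional for s in summaries]),
        mean_pct_single=mean(singles) if singles else None,
        mean_pct_multiple=mean(multiples) if multiples else None,
    )


def compare_groups(
    values_by_group: dict[str, list[float]],
    alpha_normality: float = 0.05,
) -> TestResult:
    """Dispatch and run the between-group test on per-sample values."""
    groups = {k: list(map(float, v)) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    samples = list(groups.values())

    def _normal(vals: list[float]) -> bool:
        if len(set(vals)) == 1:
            return True   # Shapiro is undefined on constant data
        return stats.shapiro(vals).pvalue >= alpha_normality

    all_normal = all(_normal(v) for v in samples)
    constant_all = all(len(set(v)) == 1 for v in samples)
    if len(set(map(tuple, samples))) == 1:
        # identical samples: no evidence of any difference
        name = "t_test_two_tailed" if len(samples) == 2 else "anova_one_way"
        return TestResult(name, 0.0, 1.0, "ns",
                          {"normal": True, "homoscedastic": True})
    homoscedastic = True
    if all_normal and len(samples) >= 3 and not constant_all:
        homoscedastic = stats.levene(*samples).pvalue >= alpha_normality

    screens = {"normal": all_normal, "homoscedastic": homoscedastic}
    if len(samples) == 2:
        if all_normal:
            res = stats.ttest_ind(*samples)
            name = "t_test_two_tailed"
        else:
            res = stats.mannwhitneyu(*samples, alternative="two-sided")
            name = "mann_whitney"
    else:
        if all_normal and homoscedastic:
            res = stats.f_oneway(*samples)
            name = "anova_one_way"
        else:
            res = stats.kruskal(*samples)
            name = "kruskal_wallis"
    stat = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(p):
        stat, p = 0.0, 1.0
    return TestResult(name, stat, p, significance_label(p), screens)


def _fmt(value: float | None) -> str:
    return "NA" if value is None else f"{round3(value):.3f}"


def table_one(
    summaries_by_group: dict[str, list[SampleSummary]],
) -> pd.DataFrame:
    """Cohort table: one row per sample plus an Average row per group."""
    rows = []
    for group_id, summaries in summaries_by_group.items():
        for s in summaries:
            rows.append({
                "group": group_id,
                "sample": s.sample_id,
                "n_cells": s.n_cells,
                "n_unique_sequences": s.n_unique_sequences,
                "n_functional": s.n_functional,
                "pct_functional": _fmt(s.pct_functional),
                "pct_single": _fmt(s.pct_single),
                "pct_multiple": _fmt(s.pct_multiple),
            })
        g = aggregate_group(summaries, group_id)
        rows.append({
            "group": group_id,
            "sample": "Average",
            "n_cells": "",
            "n_unique_sequences": "",
            "n_functional": "",
            "pct_functional": _fmt(g.mean_pct_functional),
            "pct_single": _fmt(g.mean_pct_single),
            "pct_multiple": _fmt(g.mean_pct_multiple),
        })
    return pd.DataFrame(rows)
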