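"""Group statistics for aggregate localization and area comparisons.

Two analyses accompany the imaging pipelines:

* a two-sided Fisher's exact test with sample odds ratio on a 2x2
  location-by-marker contingency table (e.g. extracellular vs intracellular
  aggregates, TOM20-positive vs -negative), with a conditional-exact 95%
  confidence interval for the odds ratio;
* pairwise two-sided Wilcoxon rank-sum tests across experimental
  conditions' aggregate-area distributions, with Benjamini-Hochberg
  false-discovery-rate correction over the family of pairwise tests.

Rank tests are used because aggregate areas are heavy-tailed and
right-skewed (approximately log-normal); no distributional model beyond
ranks is fitted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are locations, columns marker status."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("invalid table: counts must be non-negative integers")
        if self.total < 1:
            raise ValueError("invalid table: total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def row_proportions(self) -> tuple[float, float]:
        """First-column proportion per row (e.g. fraction marker-positive)."""
        return (
            self.a / (self.a + self.b) if self.a + self.b else math.nan,
            self.c / (self.c + self.d) if self.c + self.d else math.nan,
        )


@dataclass
class FisherResult:
    odds_ratio: float  # sample (cross-product) OR, a*d/(b*c); may be inf/nan
    p_two_sided: float
    ci_95: tuple[float, float]
    method_note: str


@dataclass
class PairwiseComparisonResult:
    group_pair: tuple[str, str]
    statistic: float  # rank sum of the first group, on midranks
    p_raw: float
    p_adjusted: float
    n_x: int = 0
    n_y: int = 0


def sample_odds_ratio(table: ContingencyTable2x2) -> float:
    """Cross-product odds ratio a*d / (b*c); +inf when b*c = 0 < a*d."""
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def fisher_exact_2x2(
    table: ContingencyTable2x2,
    or_kind: str = "sample",
    compute_ci: bool = True,
) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities, over all tables with the
    observed margins, of every table at most as probable as the observed
    one. The reported odds ratio is the sample (cross-product) value by
    default; ``or_kind="conditional"`` reports the conditional maximum
    likelihood estimate instead. The 95% CI always comes from inverting the
    conditional exact (noncentral hypergeometric) test.

    A table with a zero margin carries no information: p = 1 by convention.
    ``compute_ci=False`` skips the CI inversion (numeric root-finding, the
    dominant cost when sweeping many tables) and reports NaN bounds.
    """
    arr = table.as_array()
    margins_ok = arr.sum(axis=0).all() and arr.sum(axis=1).all()
    if not margins_ok:
        return FisherResult(
            odds_ratio=sample_odds_ratio(table),
            p_two_sided=1.0,
            ci_95=(0.0, math.inf),
            method_note="degenerate margins: p = 1 by convention",
        )
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    if compute_ci or or_kind == "conditional":
        res = _conditional_odds_ratio(arr, kind="conditional")
        ci = res.confidence_interval(confidence_level=0.95)
        ci_pair = (float(ci.low), float(ci.high))
    else:
        ci_pair = (math.nan, math.nan)
    or_value = (
        sample_odds_ratio(table) if or_kind == "sample" else float(res.statistic)
    )
    return FisherResult(
        odds_ratio=or_value,
        p_two_sided=float(p),
        ci_95=ci_pair,
        method_note=(
            f"{or_kind} odds ratio; CI by conditional exact "
            "(noncentral hypergeometric) inversion"
        ),
    )


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(statistic, p)`` where the statistic is the rank sum of the
    first sample computed on midranks. The p-value uses the exact null
    distribution when both samples are small (min n <= 10) and untied, and
    otherwise a normal approximation with tie-corrected variance and
    continuity correction — experimental group sizes here (~100) are
    squarely in the asymptotic regime.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return w, float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adjusted_(i) = min_{j >= i} (m * p_(j) / j)`` over the ascending
    order statistics, capped at 1; ordering of raw p-values is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("invalid p-value: all p must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def compare_groups(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> list[PairwiseComparisonResult]:
    """Pairwise Wilcoxon rank-sum with BH correction across the family.

    ``table`` must have columns ``group`` and ``area_nm2``. By default all
    unordered group pairs are tested (6 pairs for 4 conditions); the BH
    family is exactly the set of tested pairs. Results are sorted by pair
    label.
    """
    if not {"group", "area_nm2"} <= set(table.columns):
        raise ValueError("table must have columns 'group' and 'area_nm2'")
    groups = {g: sub["area_nm2"].to_numpy() for g, sub in table.groupby("group")}
    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    else:
        pairs = [tuple(sorted(p)) for p in pairs]
        for g in {g for p in pairs for g in p}:
            if g not in groups:
                raise KeyError(f"missing group: {g!r}")
    pairs = sorted(pairs)
    stats_p = [wilcoxon_rank_sum(groups[g1], groups[g2]) for g1, g2 in pairs]
    adjusted = bh_adjust([p for _, p in stats_p])
    return [
        PairwiseComparisonResult(
            group_pair=(g1, g2),
            statistic=w,
            p_raw=p,
            p_adjusted=float(pa),
            n_x=len(groups[g1]),
            n_y=len(groups[g2]),
        )
        for (g1, g2), (w, p), pa in zip(pairs, stats_p, adjusted)
    ]


def comparison_table(results: list[PairwiseComparisonResult]) -> pd.DataFrame:
    """Flatten pairwise results into a DataFrame for CSV export."""
    return pd.DataFrame(
        {
            "group_1": [r.group_pair[0] for r in results],
            "group_2": [r.group_pair[1] for r in results],
            "n_1": [r.n_x for r in results],
            "n_2": [r.n_y for r in results],
            "rank_sum": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
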