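"""Group-level statistics over haplotype classes.

Covers expansion-carriership enrichment between two groups (two-
proportion chi-square with and without continuity correction plus
Fisher's exact), a tie-corrected Kruskal-Wallis test across groups, and
pairwise two-sided Mann-Whitney U tests against a reference group.
Medians are computed on assigned, non-expanded lengths only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .haplotype_groups import CLASSES, HaplotypeClass

__all__ = [
    "GroupStats",
    "GroupSummary",
    "EnrichmentResult",
    "RankTestResult",
    "expansion_enrichment",
    "expansion_enrichment_from_counts",
    "kruskal_wallis_lengths",
    "kruskal_statistic",
    "pairwise_length_tests",
]


@dataclass
class GroupStats:
    """Assigned-haplotype tallies for one class."""

    n_haplotypes: int = 0
    n_expanded: int = 0
    lengths: list[int] = field(default_factory=list)
    n_unassigned: int = 0

    @property
    def median_length(self) -> float | None:
        return float(np.median(self.lengths)) if self.lengths else None

    @property
    def iqr(self) -> tuple[float, float] | None:
        if not self.lengths:
            return None
        lo, hi = np.percentile(self.lengths, [25, 75])
        return float(lo), float(hi)

    @property
    def pct_expanded(self) -> float | None:
        if self.n_haplotypes == 0:
            return None
        return 100.0 * self.n_expanded / self.n_haplotypes


@dataclass
class GroupSummary:
    groups: dict[HaplotypeClass, GroupStats] = field(default_factory=dict)

    def stats(self, cls: HaplotypeClass) -> GroupStats:
        return self.groups.setdefault(cls, GroupStats())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in CLASSES:
            g = self.groups.get(cls, GroupStats())
            med = g.median_length
            rows.append(
                {
                    "class": cls.name,
                    "n": g.n_haplotypes,
                    "n_expanded": g.n_expanded,
                    "pct_expanded": "NA" if g.pct_expanded is None else f"{g.pct_expanded:.4g}",
                    "median_len": "NA" if med is None else f"{med:g}",
                    "n_unassigned": g.n_unassigned,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichmentResult:
    prop_a: float
    prop_b: float
    risk_ratio: float  # nan when undefined
    odds_ratio: float
    chi2_p: float  # plain (uncorrected) two-proportion chi-square
    chi2_p_corrected: float  # Yates continuity correction
    fisher_p: float
    counts: tuple[int, int, int, int]  # k_a, n_a, k_b, n_b


@dataclass(frozen=True)
class RankTestResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    medians: tuple[float | None, ...]
    df: int | None = None
    note: str | None = None


def expansion_enrichment_from_counts(
    k_a: int, n_a: int, k_b: int, n_b: int
) -> EnrichmentResult:
    """Enrichment of expansion carriership: group a (k_a/n_a) vs b (k_b/n_b)."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both groups must be nonempty")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("counts out of range")
    prop_a = k_a / n_a
    prop_b = k_b / n_b
    risk_ratio = prop_a / prop_b if prop_b > 0 else math.nan
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]])
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_ratio = float(
            np.float64(k_a * (n_b - k_b)) / np.float64(k_b * (n_a - k_a))
        )
    def _chi2(correction: bool) -> float:
        if (table.sum(axis=0) == 0).any():
            return math.nan  # zero margin: test undefined
        if prop_a == prop_b:
            return 1.0
        return float(stats.chi2_contingency(table, correction=correction)[1])
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return EnrichmentResult(
        prop_a=prop_a,
        prop_b=prop_b,
        risk_ratio=risk_ratio,
        odds_ratio=odds_ratio,
        chi2_p=_chi2(False),
        chi2_p_corrected=_chi2(True),
        fisher_p=fisher_p,
        counts=(k_a, n_a, k_b, n_b),
    )


def expansion_enrichment(
    summary: GroupSummary, class_a: HaplotypeClass, class_b: HaplotypeClass
) -> EnrichmentResult:
    ga = summary.stats(class_a)
    gb = summary.stats(class_b)
    return expansion_enrichment_from_counts(
        ga.n_expanded, ga.n_haplotypes, gb.n_expanded, gb.n_haplotypes
    )


def kruskal_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        start += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1 - ((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if correction == 0:
        return 0.0  # every observation identical
    return float(h / correction)


def _kruskal_permutation_p(groups: list[np.ndarray], observed: float) -> float:
    """Exact permutation P over all distinct group assignments."""
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    idx = range(pooled.size)
    hits = 0
    total = 0
    def assignments(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in assignments(rest, sizes_left[1:]):
                yield [combo] + tail
    for assign in assignments(tuple(idx), sizes):
        perm_groups = [pooled[list(c)] for c in assign]
        h = kruskal_statistic(perm_groups)
        total += 1
        if h >= observed - 1e-12:
            hits += 1
    return hits / total


def kruskal_wallis_lengths(
    summary: GroupSummary,
    classes: list[HaplotypeClass] | None = None,
    method: str = "chi2",
) -> RankTestResult:
    """Kruskal-Wallis over non-expanded assigned lengths of the groups.

    ``method``: "chi2" (asymptotic, default), "permutation" (exact,
    small samples only), or "auto" (exact when total n <= 8).
    """
    if classes is None:
        classes = [c for c in CLASSES if summary.stats(c).lengths]
    groups = [np.asarray(summary.stats(c).lengths, dtype=float) for c in classes]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    h = kruskal_statistic(groups)
    n_total = sum(g.size for g in groups)
    df = len(groups) - 1
    if method == "auto":
        method = "permutation" if n_total <= 8 else "chi2"
    if method == "permutation":
        p = _kruskal_permutation_p(groups, h)
    elif method == "chi2":
        p = 1.0 if h == 0.0 else float(stats.chi2.sf(h, df))
    else:
        raise ValueError(f"unknown method {method!r}")
    medians = tuple(float(np.median(g)) for g in groups)
    return RankTestResult(
        test=f"kruskal-wallis[{method}]",
        groups=tuple(c.name for c in classes),
        statistic=h,
        p_value=min(p, 1.0) if not math.isnan(p) else p,
        medians=medians,
        df=df,
    )


def pairwise_length_tests(
    summary: GroupSummary,
    reference_class: HaplotypeClass = HaplotypeClass.FOUNDER_RISK,
    bonferroni: bool = False,
) -> list[RankTestResult]:
    """Two-sided Mann-Whitney U of the reference group against each other
    group.  P-values are raw by default (no multiplicity correction)."""
    ref = summary.stats(reference_class)
    if not ref.lengths:
        raise ValueError(f"reference group {reference_class.name} has no lengths")
    others = [c for c in CLASSES if c is not reference_class]
    results: list[RankTestResult] = []
    n_comparisons = sum(1 for c in others if summary.stats(c).lengths)
    for cls in others:
        g = summary.stats(cls)
        if not g.lengths:
            results.append(
                RankTestResult(
                    test="mann-whitney",
                    groups=(reference_class.name, cls.name),
                    statistic=math.nan,
                    p_value=math.nan,
                    medians=(ref.median_length, None),
                    note="skipped: empty comparison group",
                )
            )
            continue
        x = np.asarray(ref.lengths, dtype=float)
        y = np.asarray(g.lengths, dtype=float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        p = float(res.pvalue)
        if bonferroni:
            p = min(1.0, p * n_comparisons)
        results.append(
            RankTestResult(
                test="mann-whitney",
                groups=(reference_class.name, cls.name),
                statistic=float(res.statistic),
                p_value=p,
                medians=(ref.median_length, g.median_length),
            )
        )
    return results
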