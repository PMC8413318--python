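"""Bayesian assignment of unordered repeat-length pairs to haplotypes.

The classifier is trained at superclass level (ancestral vs founder) on
superclass-homozygous, non-expanded individuals, whose allele-to-
haplotype mapping is unambiguous.  For every other sample the two
possible allele->haplotype configurations are scored by the product of
class-conditional likelihoods; the max-posterior configuration is
accepted when its posterior clears a threshold or the two measured
lengths are close enough for the choice to be immaterial.

Expanded alleles (length unknown, beyond the pathological threshold)
enter the likelihood through per-superclass expansion weights rather
than through the length PMFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_stats import GroupSummary
from .haplotype_groups import (
    HaplotypeClass,
    Superclass,
    TaggingScheme,
    classify_cohort,
)
from .io_formats import (
    PhasedGenotypeMatrix,
    RepeatAllele,
    RepeatGenotypeTable,
)

__all__ = [
    "LengthPMF",
    "PhasingConfig",
    "HaplotypeAssignment",
    "PhasingResult",
    "PhasingReport",
    "pmf_from_counts",
    "train_length_pmfs",
    "assign_lengths",
    "phase_cohort",
    "summarize_groups",
]


@dataclass(frozen=True)
class LengthPMF:
    """Smoothed probability mass over repeat lengths 1..l_max."""

    superclass: Superclass
    probs: tuple[float, ...]  # probs[l-1] = P(length == l)
    alpha: float

    def __post_init__(self) -> None:
        total = sum(self.probs)
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError(f"PMF must sum to 1, got {total!r}")
        if any(p < 0 for p in self.probs):
            raise ValueError("PMF has negative mass")
        if self.alpha > 0 and any(p == 0 for p in self.probs):
            raise ValueError("smoothed PMF must be strictly positive")

    @property
    def l_max(self) -> int:
        return len(self.probs)

    def prob(self, length: int) -> float:
        if not 1 <= length <= self.l_max:
            return 0.0
        return self.probs[length - 1]

    def median(self) -> int:
        cdf = np.cumsum(self.probs)
        return int(np.searchsorted(cdf, 0.5) + 1)


@dataclass(frozen=True)
class PhasingConfig:
    posterior_threshold: float = 0.8
    length_gap: int = 3
    pathological_threshold: int = 30
    alpha: float = 1.0
    # likelihood of an EXPANDED allele given the haplotype superclass;
    # defaults follow the observed 30/31 founder vs ancestral split
    expansion_weights: dict[Superclass, float] = field(
        default_factory=lambda: {Superclass.FOUNDER: 0.968, Superclass.ANCESTRAL: 0.032}
    )

    def __post_init__(self) -> None:
        if not 0.5 < self.posterior_threshold <= 1.0:
            raise ValueError(
                f"posterior_threshold must be in (0.5, 1], got {self.posterior_threshold}"
            )
        if self.length_gap < 0:
            raise ValueError("length_gap must be >= 0")
        if self.pathological_threshold < 1:
            raise ValueError("pathological_threshold must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        for s in Superclass:
            w = self.expansion_weights.get(s)
            if w is None or not 0 < w <= 1:
                raise ValueError(f"expansion weight for {s.name} must be in (0, 1]")


@dataclass(frozen=True)
class HaplotypeAssignment:
    hap_class: HaplotypeClass
    allele: RepeatAllele | None  # None = unassigned
    posterior: float

    @property
    def is_assigned(self) -> bool:
        return self.allele is not None


@dataclass(frozen=True)
class PhasingResult:
    sample: str
    assignments: tuple[HaplotypeAssignment, HaplotypeAssignment]

    @property
    def is_assigned(self) -> bool:
        return self.assignments[0].is_assigned


@dataclass
class PhasingReport:
    n_samples: int
    n_classified_haplotypes: int
    n_assigned_haplotypes: int
    excluded_samples: list[str]

    @property
    def mapping_rate(self) -> float | None:
        if self.n_classified_haplotypes == 0:
            return None
        return self.n_assigned_haplotypes / self.n_classified_haplotypes


def pmf_from_counts(
    counts: dict[int, int], alpha: float, l_max: int, superclass: Superclass
) -> LengthPMF:
    """Additive smoothing: P(l) = (count(l) + alpha) / (N + alpha * l_max)."""
    bad = [l for l in counts if not 1 <= l <= l_max]
    if bad:
        raise ValueError(f"lengths outside 1..{l_max}: {bad}")
    n = sum(counts.values())
    denom = n + alpha * l_max
    if denom == 0:
        raise ValueError("empty counts with alpha=0")
    probs = tuple((counts.get(l, 0) + alpha) / denom for l in range(1, l_max + 1))
    return LengthPMF(superclass=superclass, probs=probs, alpha=alpha)


def train_length_pmfs(
    repeat_table: RepeatGenotypeTable,
    class_pairs: dict[str, tuple[HaplotypeClass, HaplotypeClass]],
    config: PhasingConfig = PhasingConfig(),
) -> dict[Superclass, LengthPMF]:
    """Train one PMF per superclass from superclass-homozygous individuals.

    Training individuals have both haplotypes in the same superclass and
    no expanded (or above-threshold) allele; their two alleles are pooled.
    """
    counts: dict[Superclass, dict[int, int]] = {s: {} for s in Superclass}
    for sample, (c1, c2) in class_pairs.items():
        if HaplotypeClass.UNKNOWN in (c1, c2) or sample not in repeat_table:
            continue
        if c1.superclass is not c2.superclass:
            continue
        a, b = repeat_table.pair(sample)
        if a.is_expanded or b.is_expanded:
            continue
        if max(a.length, b.length) > config.pathological_threshold:  # type: ignore[arg-type]
            continue
        sc = c1.superclass
        for allele in (a, b):
            counts[sc][allele.length] = counts[sc].get(allele.length, 0) + 1  # type: ignore[index]
    pmfs: dict[Superclass, LengthPMF] = {}
    for sc in Superclass:
        if not counts[sc]:
            raise ValueError(
                f"no {sc.name} superclass-homozygous training individuals"
            )
        pmfs[sc] = pmf_from_counts(
            counts[sc], config.alpha, config.pathological_threshold, sc
        )
    return pmfs


def _likelihood(
    allele: RepeatAllele, sc: Superclass, pmfs: dict[Superclass, LengthPMF], config: PhasingConfig
) -> float:
    if allele.is_expanded:
        return config.expansion_weights[sc]
    return pmfs[sc].prob(allele.length)  # type: ignore[arg-type]


def assign_lengths(
    class_pair: tuple[HaplotypeClass, HaplotypeClass],
    repeat_pair: tuple[RepeatAllele, RepeatAllele],
    pmfs: dict[Superclass, LengthPMF],
    config: PhasingConfig = PhasingConfig(),
    sample: str = "",
) -> PhasingResult:
    """Assign the unordered allele pair to the two classified haplotypes.

    Configurations c1 = (a->h1, b->h2) and c2 = (b->h1, a->h2) are
    scored by products of superclass-conditional likelihoods; the best
    configuration is accepted when its posterior >= the threshold, or
    when both alleles are measured and differ by at most ``length_gap``
    (the choice then cannot matter more than the gap).  Ties (posterior
    exactly 0.5) put the shorter allele on the first-listed haplotype.
    Identical-class pairs are always accepted: the orientation is
    immaterial.
    """
    c1, c2 = class_pair
    if HaplotypeClass.UNKNOWN in (c1, c2):
        raise ValueError("cannot assign lengths to an UNKNOWN haplotype")
    a, b = repeat_pair
    la = _likelihood(a, c1.superclass, pmfs, config) * _likelihood(
        b, c2.superclass, pmfs, config
    )
    lb = _likelihood(b, c1.superclass, pmfs, config) * _likelihood(
        a, c2.superclass, pmfs, config
    )
    total = la + lb
    post_ab = la / total if total > 0 else 0.5
    best_posterior = max(post_ab, 1.0 - post_ab)

    both_measured = not (a.is_expanded or b.is_expanded)
    gap_ok = both_measured and abs(a.length - b.length) <= config.length_gap  # type: ignore[arg-type]
    same_class = c1 is c2
    accept = same_class or best_posterior >= config.posterior_threshold or gap_ok
    if not accept:
        return PhasingResult(
            sample=sample,
            assignments=(
                HaplotypeAssignment(c1, None, best_posterior),
                HaplotypeAssignment(c2, None, best_posterior),
            ),
        )
    if post_ab > 0.5:
        first, second = a, b
    elif post_ab < 0.5:
        first, second = b, a
    else:
        # exact tie: shorter allele to the first-listed haplotype
        first, second = sorted((a, b), key=RepeatAllele.sort_key)
    return PhasingResult(
        sample=sample,
        assignments=(
            HaplotypeAssignment(c1, first, best_posterior),
            HaplotypeAssignment(c2, second, best_posterior),
        ),
    )


def phase_cohort(
    matrix: PhasedGenotypeMatrix,
    repeat_table: RepeatGenotypeTable,
    scheme: TaggingScheme = TaggingScheme(),
    config: PhasingConfig = PhasingConfig(),
    pmfs: dict[Superclass, LengthPMF] | None = None,
) -> tuple[list[PhasingResult], PhasingReport]:
    """classify -> train -> assign over a whole cohort.

    Samples lacking repeat data or with any UNKNOWN haplotype are
    excluded (reported, not fatal).  ``pmfs`` may be supplied to skip
    training (e.g. to reuse PMFs across cohorts).
    """
    classification = classify_cohort(matrix, scheme)
    usable = [
        s
        for s in matrix.samples
        if s in repeat_table
        and HaplotypeClass.UNKNOWN not in classification.pairs[s]
    ]
    excluded = [s for s in matrix.samples if s not in usable]
    if usable and pmfs is None:
        pmfs = train_length_pmfs(repeat_table, classification.pairs, config)
    results = [
        assign_lengths(
            classification.pairs[s], repeat_table.pair(s), pmfs, config, sample=s
        )
        for s in usable
    ]
    n_assigned = sum(
        1 for r in results for asn in r.assignments if asn.is_assigned
    )
    report = PhasingReport(
        n_samples=len(usable),
        n_classified_haplotypes=2 * len(usable),
        n_assigned_haplotypes=n_assigned,
        excluded_samples=excluded,
    )
    return results, report


def summarize_groups(
    results: list[PhasingResult], config: PhasingConfig = PhasingConfig()
) -> GroupSummary:
    """Per-class counts, expansion counts and non-expanded length lists.

    A measured length above the pathological threshold counts as an
    expansion.  Unassigned haplotypes are tallied per class separately.
    """
    summary = GroupSummary()
    for res in results:
        for asn in res.assignments:
            g = summary.stats(asn.hap_class)
            if asn.allele is None:
                g.n_unassigned += 1
                continue
            g.n_haplotypes += 1
            if asn.allele.is_expanded or asn.allele.length > config.pathological_threshold:  # type: ignore[operator]
                g.n_expanded += 1
            else:
                g.lengths.append(asn.allele.length)  # type: ignore[arg-type]
    return summary
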