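"""Four-group haplotype classification from tag SNPs, plus LD statistics.

Each phased haplotype is classified on two axes: founder status from a
single founder-tagging SNP, and risk status from carrying at least one
of the risk alleles.  Linkage disequilibrium between two sites is
computed from phased two-locus haplotype counts; co-carriage is a
person-level statistic over minor-allele carriers.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

from .io_formats import PhasedGenotypeMatrix

__all__ = [
    "Superclass",
    "HaplotypeClass",
    "TaggingScheme",
    "LDStats",
    "CohortClassification",
    "classify_haplotype",
    "classify_cohort",
    "ld_from_haplotype_counts",
    "ld_stats",
    "alt_allele_frequency",
]


class Superclass(enum.Enum):
    ANCESTRAL = "ANCESTRAL"
    FOUNDER = "FOUNDER"


class HaplotypeClass(enum.Enum):
    ANCESTRAL_NONRISK = "ANCESTRAL_NONRISK"
    ANCESTRAL_RISK = "ANCESTRAL_RISK"
    FOUNDER_NONRISK = "FOUNDER_NONRISK"
    FOUNDER_RISK = "FOUNDER_RISK"
    UNKNOWN = "UNKNOWN"

    @property
    def superclass(self) -> Superclass:
        if self is HaplotypeClass.UNKNOWN:
            raise ValueError("UNKNOWN haplotype has no superclass")
        return (
            Superclass.FOUNDER
            if self.name.startswith("FOUNDER")
            else Superclass.ANCESTRAL
        )

    @property
    def is_risk(self) -> bool:
        if self is HaplotypeClass.UNKNOWN:
            raise ValueError("UNKNOWN haplotype has no risk status")
        return self.name.endswith("_RISK")


CLASSES = (
    HaplotypeClass.ANCESTRAL_NONRISK,
    HaplotypeClass.ANCESTRAL_RISK,
    HaplotypeClass.FOUNDER_NONRISK,
    HaplotypeClass.FOUNDER_RISK,
)


@dataclass(frozen=True)
class TaggingScheme:
    """Which SNP alleles tag founder status and risk status.

    The founder tag is a single SNP; any number of risk SNPs may be
    supplied and a haplotype is "risk" when it carries at least one of
    their risk alleles.
    """

    founder_snp: tuple[str, str] = ("rs3849942", "T")
    risk_snps: tuple[tuple[str, str], ...] = (
        ("rs147211831", "A"),
        ("rs117204439", "C"),
    )

    def __post_init__(self) -> None:
        risk_ids = [r for r, _ in self.risk_snps]
        if self.founder_snp[0] in risk_ids:
            raise ValueError("founder SNP cannot also be a risk SNP")
        if len(set(risk_ids)) != len(risk_ids):
            raise ValueError("duplicate risk SNPs")
        for _, allele in (self.founder_snp, *self.risk_snps):
            if len(allele) != 1:
                raise ValueError(f"tag alleles must be single characters, got {allele!r}")

    @property
    def rsids(self) -> tuple[str, ...]:
        return (self.founder_snp[0],) + tuple(r for r, _ in self.risk_snps)


@dataclass(frozen=True)
class LDStats:
    r2: float
    d_prime: float
    d: float
    co_carriage: float | None
    n_haplotypes: int


def classify_haplotype(
    alleles_at_tags: dict[str, str | None], scheme: TaggingScheme
) -> HaplotypeClass:
    """Classify one haplotype from its tag-SNP alleles.

    ``None`` at any tag gives UNKNOWN.  Alleles must be supplied for
    every tag rsID of the scheme.
    """
    missing_keys = [r for r in scheme.rsids if r not in alleles_at_tags]
    if missing_keys:
        raise KeyError(f"no allele supplied for tag SNP(s): {missing_keys}")
    values = [alleles_at_tags[r] for r in scheme.rsids]
    for v in values:
        if v is not None and (not isinstance(v, str) or len(v) != 1):
            raise ValueError(f"allele must be a single-character string or None, got {v!r}")
    if any(v is None for v in values):
        return HaplotypeClass.UNKNOWN
    founder_rsid, founder_allele = scheme.founder_snp
    founder = alleles_at_tags[founder_rsid] == founder_allele
    risk = any(alleles_at_tags[r] == a for r, a in scheme.risk_snps)
    if founder:
        return HaplotypeClass.FOUNDER_RISK if risk else HaplotypeClass.FOUNDER_NONRISK
    return HaplotypeClass.ANCESTRAL_RISK if risk else HaplotypeClass.ANCESTRAL_NONRISK


@dataclass
class CohortClassification:
    """Per-sample class pairs plus haplotype group counts."""

    pairs: dict[str, tuple[HaplotypeClass, HaplotypeClass]]
    counts: Counter = field(default_factory=Counter)
    excluded: list[str] = field(default_factory=list)

    @property
    def n_classified_haplotypes(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[HaplotypeClass, float]:
        total = self.n_classified_haplotypes
        return {c: self.counts.get(c, 0) / total for c in CLASSES}


def classify_cohort(
    matrix: PhasedGenotypeMatrix, scheme: TaggingScheme
) -> CohortClassification:
    """Classify both haplotypes of every sample; UNKNOWNs are excluded
    from the counts and reported, never imputed."""
    for rsid in scheme.rsids:
        matrix.site(rsid)  # KeyError if the panel lacks a tag SNP
    pairs: dict[str, tuple[HaplotypeClass, HaplotypeClass]] = {}
    counts: Counter = Counter()
    excluded: list[str] = []
    for sample in matrix.samples:
        hap1, hap2 = matrix.haplotype_alleles(sample)
        c1 = classify_haplotype({r: hap1[r] for r in scheme.rsids}, scheme)
        c2 = classify_haplotype({r: hap2[r] for r in scheme.rsids}, scheme)
        pairs[sample] = (c1, c2)
        if HaplotypeClass.UNKNOWN in (c1, c2):
            excluded.append(sample)
        else:
            counts[c1] += 1
            counts[c2] += 1
    return CohortClassification(pairs=pairs, counts=counts, excluded=excluded)


def ld_from_haplotype_counts(
    n_ab: int, n_aB: int, n_Ab: int, n_AB: int
) -> tuple[float, float, float]:
    """(D, D', r2) from phased two-locus haplotype counts.

    Uppercase letters denote the "A"/"B" alleles whose joint frequency
    enters D = p(AB) - p(A)p(B); D' is signed.
    """
    n = n_ab + n_aB + n_Ab + n_AB
    if n == 0:
        raise ValueError("no haplotypes")
    p_a = (n_AB + n_Ab) / n
    p_b = (n_AB + n_aB) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("LD undefined: monomorphic site")
    p_ab = n_AB / n
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return 0.0, 0.0, 0.0
    return d, d / d_max, r2


def ld_stats(
    matrix: PhasedGenotypeMatrix, rsid_a: str, rsid_b: str
) -> LDStats:
    """Pairwise LD between the alt alleles of two sites, from phased
    haplotypes, plus person-level minor-allele co-carriage.

    co_carriage = fraction of carriers of site A's minor allele that
    also carry site B's minor allele (genotype level, either haplotype).
    """
    site_a, site_b = matrix.site(rsid_a), matrix.site(rsid_b)
    counts = Counter()
    carriers_b = 0
    co_carriers = 0
    any_carrier_b = False
    for sample in matrix.samples:
        ea = matrix.entry(sample, rsid_a)
        eb = matrix.entry(sample, rsid_b)
        if ea.phased and eb.phased and not ea.is_missing and not eb.is_missing:
            for ha, hb in zip(
                (ea.allele1, ea.allele2), (eb.allele1, eb.allele2)
            ):
                counts[(ha == site_a.alt, hb == site_b.alt)] += 1
        # co-carriage needs genotypes only, not phase
        if not ea.is_missing and not eb.is_missing:
            carries_b = site_b.alt in (eb.allele1, eb.allele2)
            carries_a = site_a.alt in (ea.allele1, ea.allele2)
            if carries_b:
                any_carrier_b = True
                carriers_b += 1
                if carries_a:
                    co_carriers += 1
    if not counts:
        raise ValueError("no phased complete genotypes at both sites")
    d, d_prime, r2 = ld_from_haplotype_counts(
        counts[(False, False)],
        counts[(False, True)],
        counts[(True, False)],
        counts[(True, True)],
    )
    co = co_carriers / carriers_b if any_carrier_b else None
    n = sum(counts.values())
    return LDStats(r2=r2, d_prime=d_prime, d=d, co_carriage=co, n_haplotypes=n)


def alt_allele_frequency(matrix: PhasedGenotypeMatrix, rsid: str) -> float:
    """Alt-allele frequency over non-missing genotypes (phase agnostic)."""
    site = matrix.site(rsid)
    alt = 0
    total = 0
    for sample in matrix.samples:
        e = matrix.entry(sample, rsid)
        if e.is_missing:
            continue
        total += 2
        alt += (e.allele1 == site.alt) + (e.allele2 == site.alt)
    if total == 0:
        raise ValueError(f"{rsid}: no called genotypes")
    return alt / total
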