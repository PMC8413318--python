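from __future__ import annotations

import pytest

from c9hap.haplotype_groups import TaggingScheme
from c9hap.io_formats import (
    GenotypeEntry,
    PhasedGenotypeMatrix,
    VariantSite,
)
from c9hap.synthetic_cohort import DEFAULT_SITES

TAG_SITES = list(DEFAULT_SITES)


def matrix_from_haplotypes(hap_pairs, phased=True, sites=None):
    """Build a matrix from [(hap1_alleles, hap2_alleles), ...] where each
    haplotype is a (rs3849942, rs147211831, rs117204439) allele triple."""
    sites = sites or TAG_SITES
    samples = [f"S{i + 1}" for i in range(len(hap_pairs))]
    entries = []
    for hap1, hap2 in hap_pairs:
        entries.append(
            [
                GenotypeEntry(hap1[j], hap2[j], phased)
                for j in range(len(sites))
            ]
        )
    return PhasedGenotypeMatrix(samples=samples, sites=list(sites), entries=entries)


@pytest.fixture
def scheme():
    return TaggingScheme()


@pytest.fixture
def toy_matrix():
    # S1: founder-risk | ancestral non-risk; S2: ancestral hom; S3: founder non-risk het
    return matrix_from_haplotypes(
        [
            (("T", "A", "T"), ("C", "C", "T")),
            (("C", "C", "T"), ("C", "C", "T")),
            (("T", "C", "T"), ("C", "C", "T")),
        ]
    )


@pytest.fixture
def two_site_matrix_factory():
    """Matrix over two generic biallelic sites from phased haplotype pairs."""
    sites = [
        VariantSite("rsA", "1", 100, "G", "A"),
        VariantSite("rsB", "1", 200, "G", "C"),
    ]

    def build(hap_pairs):
        samples = [f"P{i + 1}" for i in range(len(hap_pairs))]
        entries = [
            [
                GenotypeEntry(h1[0], h2[0], True),
                GenotypeEntry(h1[1], h2[1], True),
            ]
            for h1, h2 in hap_pairs
        ]
        return PhasedGenotypeMatrix(samples=samples, sites=sites, entries=entries)

    return build
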