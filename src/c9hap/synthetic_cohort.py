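"""Synthetic cohorts with the statistical structure the pipeline assumes.

Per sample, two haplotype classes are drawn independently (Hardy-
Weinberg); each haplotype draws an expansion flag from its class-
specific probability, otherwise a repeat length from its class PMF.
Tag-SNP alleles are emitted consistently with the class (risk
haplotypes draw which risk allele(s) they carry); repeat measurements
are serialized as an unordered pair, reproducing the fragment-analysis
loss of phase information (equal-length and expanded alleles collapse
to a single band).

A truth table keeps the haplotype-resolved classes and alleles so
generated cohorts can act as oracles for parameter-recovery tests.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotype_groups import CLASSES, HaplotypeClass
from .io_formats import (
    EXPANDED,
    GenotypeEntry,
    PhasedGenotypeMatrix,
    RepeatAllele,
    RepeatGenotypeTable,
    VariantSite,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "triangular_pmf",
    "simulate_cohort",
    "simulate_case_control",
    "expected_co_carriage",
]

L_MAX = 30

# GRCh37 positions; the founder-tag position is metadata only and
# configurable through SimulationConfig.sites.
DEFAULT_SITES = (
    VariantSite("rs3849942", "9", 27543384, "C", "T"),
    VariantSite("rs147211831", "9", 27436084, "C", "A"),
    VariantSite("rs117204439", "9", 27607973, "T", "C"),
)


def triangular_pmf(lo: int, mode: int, hi: int, l_max: int = L_MAX) -> np.ndarray:
    """Discrete triangular PMF on lo..hi peaked at mode, over support 1..l_max."""
    if not 1 <= lo <= mode <= hi <= l_max:
        raise ValueError(f"need 1 <= lo <= mode <= hi <= {l_max}")
    probs = np.zeros(l_max)
    for l in range(lo, hi + 1):
        probs[l - 1] = (l - lo + 1) if l <= mode else (hi - l + 1)
    return probs / probs.sum()


def _default_length_pmfs() -> dict[HaplotypeClass, np.ndarray]:
    ancestral = np.zeros(L_MAX)
    ancestral[[1, 2, 3]] = [0.70, 0.20, 0.10]  # lengths 2-4, median 2
    return {
        HaplotypeClass.ANCESTRAL_NONRISK: ancestral,
        HaplotypeClass.ANCESTRAL_RISK: ancestral.copy(),
        HaplotypeClass.FOUNDER_NONRISK: triangular_pmf(5, 8, 11),  # median 8
        HaplotypeClass.FOUNDER_RISK: triangular_pmf(9, 12, 15),  # median 12
    }


@dataclass
class SimulationConfig:
    class_frequencies: dict[HaplotypeClass, float] = field(
        default_factory=lambda: {
            HaplotypeClass.ANCESTRAL_NONRISK: 0.741,
            HaplotypeClass.ANCESTRAL_RISK: 0.006,
            HaplotypeClass.FOUNDER_NONRISK: 0.227,
            HaplotypeClass.FOUNDER_RISK: 0.026,
        }
    )
    length_pmfs: dict[HaplotypeClass, np.ndarray] = field(
        default_factory=_default_length_pmfs
    )
    expansion_probs: dict[HaplotypeClass, float] = field(
        default_factory=lambda: {
            HaplotypeClass.ANCESTRAL_NONRISK: 0.0006,
            HaplotypeClass.ANCESTRAL_RISK: 0.0,
            HaplotypeClass.FOUNDER_NONRISK: 0.022,
            HaplotypeClass.FOUNDER_RISK: 0.217,
        }
    )
    # Which risk allele(s) a risk haplotype carries; p_both is calibrated
    # so person-level co-carriage of the two risk alleles is ~0.48 at the
    # default class frequencies (see expected_co_carriage).
    p_risk_a_only: float = 0.345
    p_risk_c_only: float = 0.345
    p_risk_both: float = 0.310
    missing_rate: float = 0.0
    # case/control enrichment targets: alt-allele frequency of the
    # calibration SNP in cases and controls; None disables enrichment
    maf_target_snp: str = "rs117204439"
    case_maf: float | None = 0.039
    control_maf: float | None = 0.015
    sites: tuple[VariantSite, ...] = DEFAULT_SITES

    def validate(self) -> None:
        freqs = [self.class_frequencies.get(c, -1.0) for c in CLASSES]
        if any(f < 0 for f in freqs) or not math.isclose(sum(freqs), 1.0, abs_tol=1e-9):
            raise ValueError("class frequencies must be nonnegative and sum to 1")
        for cls in CLASSES:
            pmf = np.asarray(self.length_pmfs[cls], dtype=float)
            if pmf.shape != (L_MAX,) or np.any(pmf < 0) or not math.isclose(
                pmf.sum(), 1.0, abs_tol=1e-9
            ):
                raise ValueError(f"length PMF for {cls.name} must sum to 1 over 1..{L_MAX}")
            p = self.expansion_probs[cls]
            if not 0 <= p <= 1:
                raise ValueError(f"expansion probability for {cls.name} out of [0, 1]")
        carry = (self.p_risk_a_only, self.p_risk_c_only, self.p_risk_both)
        if any(p < 0 for p in carry) or not math.isclose(sum(carry), 1.0, abs_tol=1e-9):
            raise ValueError("risk-allele carry probabilities must sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for maf in (self.case_maf, self.control_maf):
            if maf is not None and not 0 < maf < 1:
                raise ValueError("target MAFs must be in (0, 1)")
        if {s.rsid for s in self.sites} != {
            "rs3849942",
            "rs147211831",
            "rs117204439",
        }:
            raise ValueError("sites must cover the three default tag SNPs")

    def to_dict(self) -> dict:
        """JSON-serializable view (used for manifest hashing)."""
        return {
            "class_frequencies": {c.name: self.class_frequencies[c] for c in CLASSES},
            "length_pmfs": {
                c.name: [float(p) for p in self.length_pmfs[c]] for c in CLASSES
            },
            "expansion_probs": {c.name: self.expansion_probs[c] for c in CLASSES},
            "p_risk_a_only": self.p_risk_a_only,
            "p_risk_c_only": self.p_risk_c_only,
            "p_risk_both": self.p_risk_both,
            "missing_rate": self.missing_rate,
            "maf_target_snp": self.maf_target_snp,
            "case_maf": self.case_maf,
            "control_maf": self.control_maf,
            "sites": [
                [s.rsid, s.chrom, s.pos, s.ref, s.alt] for s in self.sites
            ],
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def risk_c_fraction(self) -> float:
        """P(a risk haplotype carries the rs117204439-C allele)."""
        return self.p_risk_c_only + self.p_risk_both

    def risk_class_frequency(self) -> float:
        return (
            self.class_frequencies[HaplotypeClass.ANCESTRAL_RISK]
            + self.class_frequencies[HaplotypeClass.FOUNDER_RISK]
        )


@dataclass
class TruthTable:
    """Haplotype-resolved ground truth for every generated sample."""

    frame: pd.DataFrame  # sample, class1, class2, allele1, allele2

    def class_pair(self, sample: str) -> tuple[HaplotypeClass, HaplotypeClass]:
        row = self.frame.loc[self.frame["sample"] == sample].iloc[0]
        return HaplotypeClass[row["class1"]], HaplotypeClass[row["class2"]]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def expected_co_carriage(config: SimulationConfig) -> float:
    """Closed-form person-level P(carries risk allele A | carries C) under HWE."""
    f_r = config.risk_class_frequency()
    h_both = f_r * config.p_risk_both
    h_c = f_r * config.p_risk_c_only
    h_a = f_r * config.p_risk_a_only
    h_none = 1.0 - f_r
    p_no_c = (1.0 - h_both - h_c) ** 2
    p_no_a = (1.0 - h_both - h_a) ** 2
    p_neither = h_none**2
    p_c = 1.0 - p_no_c
    p_a_and_c = 1.0 - p_no_c - p_no_a + p_neither
    return p_a_and_c / p_c


_RISK_PATTERNS = ((True, False), (False, True), (True, True))  # (carries A, carries C)


def _draw_haplotypes(
    rng: np.random.Generator,
    config: SimulationConfig,
    freqs: np.ndarray,
    n_haps: int,
):
    """Vectorized haplotype draws: classes, alleles, tag patterns."""
    class_idx = rng.choice(len(CLASSES), size=n_haps, p=freqs)
    exp_p = np.array([config.expansion_probs[c] for c in CLASSES])
    expanded = rng.random(n_haps) < exp_p[class_idx]
    lengths = np.zeros(n_haps, dtype=int)
    for k, cls in enumerate(CLASSES):
        mask = class_idx == k
        if mask.any():
            lengths[mask] = rng.choice(
                np.arange(1, L_MAX + 1), size=mask.sum(), p=config.length_pmfs[cls]
            )
    carry = rng.choice(
        3,
        size=n_haps,
        p=[config.p_risk_a_only, config.p_risk_c_only, config.p_risk_both],
    )
    return class_idx, expanded, lengths, carry


def _emit(
    config: SimulationConfig,
    sample_ids: list[str],
    class_idx: np.ndarray,
    expanded: np.ndarray,
    lengths: np.ndarray,
    carry: np.ndarray,
) -> tuple[PhasedGenotypeMatrix, TruthTable, list[tuple[RepeatAllele, RepeatAllele]]]:
    sites = {s.rsid: s for s in config.sites}
    founder, snp_a, snp_c = (
        sites["rs3849942"],
        sites["rs147211831"],
        sites["rs117204439"],
    )
    n = len(sample_ids)
    entries: list[list[GenotypeEntry]] = []
    truth_rows = []
    pairs: list[tuple[RepeatAllele, RepeatAllele]] = []
    for i in range(n):
        hap_alleles = []
        per_site: dict[str, list[str]] = {r: [] for r in sites}
        for h in (2 * i, 2 * i + 1):
            cls = CLASSES[class_idx[h]]
            allele = EXPANDED if expanded[h] else RepeatAllele.measured(int(lengths[h]))
            hap_alleles.append((cls, allele))
            per_site[founder.rsid].append(
                founder.alt if cls.superclass.name == "FOUNDER" else founder.ref
            )
            if cls.is_risk:
                has_a, has_c = _RISK_PATTERNS[carry[h]]
            else:
                has_a = has_c = False
            per_site[snp_a.rsid].append(snp_a.alt if has_a else snp_a.ref)
            per_site[snp_c.rsid].append(snp_c.alt if has_c else snp_c.ref)
        entries.append(
            [
                GenotypeEntry(per_site[s.rsid][0], per_site[s.rsid][1], True)
                for s in config.sites
            ]
        )
        (c1, a1), (c2, a2) = hap_alleles
        truth_rows.append(
            {
                "sample": sample_ids[i],
                "class1": c1.name,
                "class2": c2.name,
                "allele1": str(a1),
                "allele2": str(a2),
            }
        )
        pairs.append((a1, a2))
    matrix = PhasedGenotypeMatrix(
        samples=list(sample_ids), sites=list(config.sites), entries=entries
    )
    truth = TruthTable(frame=pd.DataFrame(truth_rows))
    return matrix, truth, pairs


def _observed_repeat_table(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_ids: list[str],
    pairs: list[tuple[RepeatAllele, RepeatAllele]],
) -> RepeatGenotypeTable:
    missing = rng.random(len(sample_ids)) < config.missing_rate
    observed: dict[str, tuple[RepeatAllele, RepeatAllele]] = {}
    for i, sample in enumerate(sample_ids):
        if missing[i]:
            continue
        a, b = sorted(pairs[i], key=RepeatAllele.sort_key)
        observed[sample] = (a, b)
    return RepeatGenotypeTable(pairs=observed)


def simulate_cohort(
    config: SimulationConfig, n_samples: int, seed: int
) -> tuple[PhasedGenotypeMatrix, RepeatGenotypeTable, TruthTable]:
    """Generate a phased tag-SNP matrix, an observed repeat table and the truth."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    config.validate()
    rng = np.random.default_rng(seed)
    freqs = np.array([config.class_frequencies[c] for c in CLASSES])
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    draws = _draw_haplotypes(rng, config, freqs, 2 * n_samples)
    matrix, truth, pairs = _emit(config, sample_ids, *draws)
    repeat_table = _observed_repeat_table(rng, config, sample_ids, pairs)
    return matrix, repeat_table, truth


def _arm_frequencies(config: SimulationConfig, target_maf: float | None) -> np.ndarray:
    """Scale risk-class frequencies so the calibration SNP hits the target MAF."""
    freqs = np.array([config.class_frequencies[c] for c in CLASSES])
    if target_maf is None:
        return freqs
    baseline = config.risk_class_frequency() * config.risk_c_fraction()
    scale = target_maf / baseline
    risk_mask = np.array([c.is_risk for c in CLASSES])
    scaled_risk = freqs[risk_mask] * scale
    remaining = 1.0 - scaled_risk.sum()
    if remaining <= 0:
        raise ValueError(
            f"target MAF {target_maf} unattainable: risk-class frequency would exceed 1"
        )
    out = freqs.copy()
    out[risk_mask] = scaled_risk
    out[~risk_mask] = freqs[~risk_mask] * remaining / freqs[~risk_mask].sum()
    return out


def simulate_case_control(
    config: SimulationConfig, n_cases: int, n_controls: int, seed: int
) -> tuple[PhasedGenotypeMatrix, pd.DataFrame, TruthTable]:
    """Case/control cohort with risk-class enrichment calibrated to the
    configured target MAFs (controls at baseline unless overridden)."""
    if n_cases < 1 or n_controls < 1:
        raise ValueError("counts must be >= 1")
    config.validate()
    rng = np.random.default_rng(seed)
    case_freqs = _arm_frequencies(config, config.case_maf)
    ctrl_freqs = _arm_frequencies(config, config.control_maf)
    case_ids = [f"CASE{i + 1:05d}" for i in range(n_cases)]
    ctrl_ids = [f"CTRL{i + 1:05d}" for i in range(n_controls)]
    case_parts = _emit(
        config, case_ids, *_draw_haplotypes(rng, config, case_freqs, 2 * n_cases)
    )
    ctrl_parts = _emit(
        config, ctrl_ids, *_draw_haplotypes(rng, config, ctrl_freqs, 2 * n_controls)
    )
    matrix = PhasedGenotypeMatrix(
        samples=case_ids + ctrl_ids,
        sites=list(config.sites),
        entries=case_parts[0].entries + ctrl_parts[0].entries,
    )
    truth = TruthTable(
        frame=pd.concat(
            [case_parts[1].frame, ctrl_parts[1].frame], ignore_index=True
        )
    )
    phenotypes = pd.DataFrame(
        {
            "sample_id": case_ids + ctrl_ids,
            "phenotype": [1] * n_cases + [0] * n_controls,
        }
    )
    return matrix, phenotypes, truth
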