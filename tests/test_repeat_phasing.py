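from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c9hap.cohort_stats import GroupSummary
from c9hap.haplotype_groups import HaplotypeClass, Superclass, classify_cohort
from c9hap.io_formats import (
    EXPANDED,
    RepeatAllele,
    RepeatGenotypeTable,
)
from c9hap.repeat_phasing import (
    HaplotypeAssignment,
    LengthPMF,
    PhasingConfig,
    PhasingResult,
    assign_lengths,
    phase_cohort,
    pmf_from_counts,
    summarize_groups,
    train_length_pmfs,
)
from c9hap.synthetic_cohort import SimulationConfig, simulate_cohort

ANR = HaplotypeClass.ANCESTRAL_NONRISK
AR = HaplotypeClass.ANCESTRAL_RISK
FNR = HaplotypeClass.FOUNDER_NONRISK
FR = HaplotypeClass.FOUNDER_RISK


def make_pmf(superclass, spec, l_max=30):
    """PMF with prescribed probabilities; remaining mass spread uniformly."""
    probs = np.zeros(l_max)
    for length, p in spec.items():
        probs[length - 1] = p
    rest = 1.0 - probs.sum()
    free = probs == 0
    probs[free] = rest / free.sum()
    return LengthPMF(superclass=superclass, probs=tuple(probs), alpha=1.0)


@pytest.fixture
def separated_pmfs():
    return {
        Superclass.ANCESTRAL: make_pmf(Superclass.ANCESTRAL, {2: 0.8, 8: 0.01}),
        Superclass.FOUNDER: make_pmf(Superclass.FOUNDER, {2: 0.05, 8: 0.5}),
    }


class TestPmfTraining:
    def test_additive_smoothing_hand_example(self):
        pmf = pmf_from_counts({2: 9}, alpha=1.0, l_max=30, superclass=Superclass.ANCESTRAL)
        assert pmf.prob(2) == pytest.approx(10 / 39)
        for l in range(1, 31):
            if l != 2:
                assert pmf.prob(l) == pytest.approx(1 / 39)
        assert sum(pmf.probs) == pytest.approx(1.0, abs=1e-12)

    def test_alpha_zero_limit(self):
        pmf = pmf_from_counts({2: 10}, alpha=0.0, l_max=30, superclass=Superclass.ANCESTRAL)
        assert pmf.prob(2) == 1.0
        assert pmf.prob(3) == 0.0

    def test_training_pools_both_alleles_of_homozygous_individuals(self):
        table = RepeatGenotypeTable(
            pairs={
                "A1": (RepeatAllele.measured(2), RepeatAllele.measured(3)),
                "F1": (RepeatAllele.measured(8), RepeatAllele.measured(8)),
                "MIX": (RepeatAllele.measured(2), RepeatAllele.measured(8)),
                "EXPANDED_IND": (RepeatAllele.measured(8), EXPANDED),
            }
        )
        class_pairs = {
            "A1": (ANR, ANR),
            "F1": (FNR, FNR),
            "MIX": (ANR, FNR),  # heterozygous superclass: not training data
            "EXPANDED_IND": (FNR, FNR),  # expanded: excluded
        }
        pmfs = train_length_pmfs(table, class_pairs, PhasingConfig())
        # ancestral counts {2:1, 3:1}; founder counts {8:2}
        assert pmfs[Superclass.ANCESTRAL].prob(2) == pytest.approx(2 / 32)
        assert pmfs[Superclass.FOUNDER].prob(8) == pytest.approx(3 / 32)

    def test_missing_superclass_raises_with_name(self):
        table = RepeatGenotypeTable(
            pairs={"A1": (RepeatAllele.measured(2), RepeatAllele.measured(2))}
        )
        with pytest.raises(ValueError, match="FOUNDER"):
            train_length_pmfs(table, {"A1": (ANR, ANR)}, PhasingConfig())

    def test_trained_founder_median_matches_generator(self):
        from c9hap.haplotype_groups import TaggingScheme

        config = SimulationConfig()
        matrix, repeats, _ = simulate_cohort(config, 2000, 7)
        classification = classify_cohort(matrix, TaggingScheme())
        pmfs = train_length_pmfs(repeats, classification.pairs, PhasingConfig())
        # generator founder mixture: FNR (median 8) dominates FR (median 12)
        mix = (
            config.class_frequencies[FNR] * config.length_pmfs[FNR]
            + config.class_frequencies[FR] * config.length_pmfs[FR]
        )
        mix = mix / mix.sum()
        gen_median = int(np.searchsorted(np.cumsum(mix), 0.5) + 1)
        assert abs(pmfs[Superclass.FOUNDER].median() - gen_median) <= 1


class TestAssignLengths:
    def test_hand_bayes_measured_pair(self, separated_pmfs):
        result = assign_lengths(
            (ANR, FNR),
            (RepeatAllele.measured(2), RepeatAllele.measured(8)),
            separated_pmfs,
        )
        expected = (0.8 * 0.5) / ((0.8 * 0.5) + (0.05 * 0.01))
        assert result.assignments[0].posterior == pytest.approx(expected)
        assert expected >= 0.8
        assert result.assignments[0].allele == RepeatAllele.measured(2)
        assert result.assignments[1].allele == RepeatAllele.measured(8)

    def test_equal_lengths_accepted_at_half(self, separated_pmfs):
        result = assign_lengths(
            (ANR, FNR),
            (RepeatAllele.measured(2), RepeatAllele.measured(2)),
            separated_pmfs,
        )
        assert result.is_assigned
        assert result.assignments[0].posterior == pytest.approx(0.5)

    def test_expanded_maps_to_founder(self, separated_pmfs):
        result = assign_lengths(
            (ANR, FR), (RepeatAllele.measured(2), EXPANDED), separated_pmfs
        )
        expected = (0.8 * 0.968) / ((0.8 * 0.968) + (0.05 * 0.032))
        assert result.assignments[0].posterior == pytest.approx(expected)
        assert result.assignments[1].allele is EXPANDED
        assert result.assignments[1].hap_class is FR

    def test_low_posterior_wide_gap_unassigned(self):
        # short allele is ambiguous between superclasses -> posterior < 0.8,
        # and lengths differ by more than 3 -> both unassigned
        pmfs = {
            Superclass.ANCESTRAL: make_pmf(Superclass.ANCESTRAL, {2: 0.1, 8: 0.05}),
            Superclass.FOUNDER: make_pmf(Superclass.FOUNDER, {2: 0.08, 8: 0.1}),
        }
        result = assign_lengths(
            (ANR, FNR), (RepeatAllele.measured(2), RepeatAllele.measured(8)), pmfs
        )
        assert not result.is_assigned
        assert result.assignments[0].posterior < 0.8
        assert result.assignments[0].allele is None
        assert result.assignments[1].allele is None

    def test_same_class_pair_always_accepted(self, separated_pmfs):
        result = assign_lengths(
            (FNR, FNR), (EXPANDED, EXPANDED), separated_pmfs
        )
        assert result.is_assigned

    def test_same_superclass_different_class_wide_gap_unassigned(self, separated_pmfs):
        result = assign_lengths(
            (FNR, FR),
            (RepeatAllele.measured(5), RepeatAllele.measured(12)),
            separated_pmfs,
        )
        assert not result.is_assigned
        assert result.assignments[0].posterior == pytest.approx(0.5)

    def test_tie_break_shorter_to_first_haplotype(self, separated_pmfs):
        result = assign_lengths(
            (FNR, FR),
            (RepeatAllele.measured(9), RepeatAllele.measured(7)),
            separated_pmfs,
        )
        assert result.is_assigned  # gap 2 <= 3
        assert result.assignments[0].allele == RepeatAllele.measured(7)
        assert result.assignments[1].allele == RepeatAllele.measured(9)

    def test_unknown_class_raises(self, separated_pmfs):
        with pytest.raises(ValueError):
            assign_lengths(
                (HaplotypeClass.UNKNOWN, FNR),
                (RepeatAllele.measured(2), RepeatAllele.measured(8)),
                separated_pmfs,
            )


@st.composite
def assignment_instances(draw):
    rng_seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(rng_seed)
    probs_a = rng.dirichlet(np.full(30, 0.5))
    probs_f = rng.dirichlet(np.full(30, 0.5))
    pmfs = {
        Superclass.ANCESTRAL: LengthPMF(Superclass.ANCESTRAL, tuple(np.maximum(probs_a, 1e-9) / np.maximum(probs_a, 1e-9).sum()), 1.0),
        Superclass.FOUNDER: LengthPMF(Superclass.FOUNDER, tuple(np.maximum(probs_f, 1e-9) / np.maximum(probs_f, 1e-9).sum()), 1.0),
    }
    classes = draw(
        st.tuples(
            st.sampled_from([ANR, AR, FNR, FR]), st.sampled_from([ANR, AR, FNR, FR])
        )
    )
    def allele(v):
        return EXPANDED if v == 0 else RepeatAllele.measured(v)
    pair = (
        allele(draw(st.integers(0, 30))),
        allele(draw(st.integers(0, 30))),
    )
    return classes, pair, pmfs


def oracle_posteriors(classes, pair, pmfs, config):
    """Independent enumeration of both configurations with pure-python floats."""
    def lik(allele, cls):
        sc = cls.superclass
        if allele.is_expanded:
            return config.expansion_weights[sc]
        return pmfs[sc].probs[allele.length - 1]
    a, b = pair
    c1, c2 = classes
    l1 = lik(a, c1) * lik(b, c2)
    l2 = lik(b, c1) * lik(a, c2)
    if l1 + l2 == 0:
        return 0.5, 0.5
    return l1 / (l1 + l2), l2 / (l1 + l2)


class TestAssignmentProperties:
    @given(assignment_instances())
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_enumeration_oracle(self, instance):
        classes, pair, pmfs = instance
        config = PhasingConfig()
        p1, p2 = oracle_posteriors(classes, pair, pmfs, config)
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)
        result = assign_lengths(classes, pair, pmfs, config)
        assert result.assignments[0].posterior == pytest.approx(max(p1, p2), abs=1e-12)
        best = max(p1, p2)
        gap_ok = (
            not pair[0].is_expanded
            and not pair[1].is_expanded
            and abs(pair[0].length - pair[1].length) <= config.length_gap
        )
        should_accept = (
            classes[0] is classes[1] or best >= config.posterior_threshold or gap_ok
        )
        assert result.is_assigned == should_accept
        if result.is_assigned and best > 0.5:
            # assigned orientation must be the max-likelihood configuration
            want_first = pair[0] if p1 > p2 else pair[1]
            assert result.assignments[0].allele == want_first

    @given(assignment_instances())
    @settings(max_examples=200, deadline=None)
    def test_invariant_to_pair_order(self, instance):
        classes, pair, pmfs = instance
        r1 = assign_lengths(classes, pair, pmfs)
        r2 = assign_lengths(classes, pair[::-1], pmfs)
        assert r1.assignments[0].posterior == pytest.approx(
            r2.assignments[0].posterior, abs=1e-12
        )
        assert [a.allele for a in r1.assignments] == [a.allele for a in r2.assignments]

    @given(assignment_instances())
    @settings(max_examples=200, deadline=None)
    def test_threshold_monotonicity(self, instance):
        classes, pair, pmfs = instance
        accepted = [
            assign_lengths(
                classes, pair, pmfs, PhasingConfig(posterior_threshold=t)
            ).is_assigned
            for t in (0.6, 0.8, 0.95, 1.0)
        ]
        # raising the threshold never turns rejection into acceptance
        for lo, hi in zip(accepted, accepted[1:]):
            assert lo or not hi


class TestPhaseCohort:
    def test_all_homozygous_rate_one(self, scheme):
        from conftest import matrix_from_haplotypes

        matrix = matrix_from_haplotypes(
            [
                (("C", "C", "T"), ("C", "C", "T")),
                (("T", "C", "T"), ("T", "C", "T")),
            ]
        )
        table = RepeatGenotypeTable(
            pairs={
                "S1": (RepeatAllele.measured(2), RepeatAllele.measured(3)),
                "S2": (RepeatAllele.measured(8), RepeatAllele.measured(9)),
            }
        )
        results, report = phase_cohort(matrix, table, scheme)
        assert report.mapping_rate == 1.0
        assert all(r.is_assigned for r in results)

    def test_empty_intersection_rate_na(self, scheme):
        from conftest import matrix_from_haplotypes

        matrix = matrix_from_haplotypes([(("C", "C", "T"), ("C", "C", "T"))])
        table = RepeatGenotypeTable(
            pairs={"OTHER": (RepeatAllele.measured(2), RepeatAllele.measured(2))}
        )
        results, report = phase_cohort(matrix, table, scheme)
        assert results == []
        assert report.mapping_rate is None
        assert report.excluded_samples == ["S1"]

    def test_synthetic_cohort_mapping_rate(self, scheme):
        matrix, repeats, _ = simulate_cohort(SimulationConfig(), 1200, 5)
        _, report = phase_cohort(matrix, repeats, scheme)
        assert report.mapping_rate is not None
        assert report.mapping_rate >= 0.95

    def test_parameter_recovery_against_truth(self, scheme):
        matrix, repeats, truth = simulate_cohort(SimulationConfig(), 2000, 9)
        results, _ = phase_cohort(matrix, repeats, scheme)
        truth_by_sample = {
            row["sample"]: (row["allele1"], row["allele2"])
            for _, row in truth.frame.iterrows()
        }
        checked = matched = 0
        for res in results:
            if not res.is_assigned:
                continue
            want = truth_by_sample[res.sample]
            got = tuple(str(a.allele) for a in res.assignments)
            same_class = res.assignments[0].hap_class is res.assignments[1].hap_class
            checked += 1
            if got == want or (same_class and sorted(got) == sorted(want)):
                matched += 1
        assert checked > 0
        assert matched / checked >= 0.95


class TestSummarizeGroups:
    def _results(self, triples):
        out = []
        for i, (cls, allele) in enumerate(triples):
            out.append(
                PhasingResult(
                    sample=f"S{i}",
                    assignments=(
                        HaplotypeAssignment(cls, allele, 0.9),
                        HaplotypeAssignment(ANR, RepeatAllele.measured(2), 0.9),
                    ),
                )
            )
        return out

    def test_hand_median_with_expansion(self):
        results = self._results(
            [
                (FR, RepeatAllele.measured(11)),
                (FR, RepeatAllele.measured(12)),
                (FR, EXPANDED),
            ]
        )
        summary = summarize_groups(results)
        g = summary.stats(FR)
        assert g.n_haplotypes == 3
        assert g.n_expanded == 1
        assert g.median_length == pytest.approx(11.5)

    def test_only_expanded_median_na(self):
        summary = summarize_groups(self._results([(FR, EXPANDED)]))
        assert summary.stats(FR).median_length is None

    def test_measured_31_counts_as_expansion(self):
        summary = summarize_groups(self._results([(FR, RepeatAllele.measured(31))]))
        g = summary.stats(FR)
        assert g.n_expanded == 1
        assert g.lengths == []

    def test_unassigned_tallied(self):
        results = [
            PhasingResult(
                sample="S0",
                assignments=(
                    HaplotypeAssignment(FR, None, 0.6),
                    HaplotypeAssignment(FNR, None, 0.6),
                ),
            )
        ]
        summary = summarize_groups(results)
        assert summary.stats(FR).n_unassigned == 1
        assert summary.stats(FR).n_haplotypes == 0


class TestConfigValidation:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            PhasingConfig(posterior_threshold=0.5)
        with pytest.raises(ValueError):
            PhasingConfig(posterior_threshold=1.01)

    def test_pmf_must_sum_to_one(self):
        with pytest.raises(ValueError):
            LengthPMF(Superclass.FOUNDER, tuple([0.5] * 3), 0.0)
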