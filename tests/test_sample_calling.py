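"""Sample-level scoring: positivity, pattern-set derivation, CNG."""

import itertools

import pytest

from alkfish.fish_signals import PatternClass, residue, token, NucleusObservation
from alkfish.sample_calling import (
    FishStatus,
    categorize_cng,
    compose_subthreshold_positive,
    copy_number_category,
    derivable,
    derive_pattern_set,
    score_sample,
    summarize_sample,
)
from alkfish.synthetic_cohort import CANONICAL_VARIANTS, reference_pattern_counts

P = PatternClass


def calls(**kwargs):
    out = []
    for name, k in kwargs.items():
        out.extend([PatternClass[name.upper()]] * k)
    return out


class TestScoreSample:
    def test_positive_at_26_percent(self):
        status, pct, _ = score_sample(calls(inversion=26, not_rearranged=74))
        assert status is FishStatus.POSITIVE
        assert pct == pytest.approx(26.0)

    def test_negative_below_cutoff(self):
        status, _, _ = score_sample(calls(inversion=14, not_rearranged=86))
        assert status is FishStatus.NEGATIVE

    def test_cutoff_is_inclusive(self):
        status, _, _ = score_sample(calls(inversion=15, not_rearranged=85))
        assert status is FishStatus.POSITIVE

    def test_insufficient_below_50_nuclei(self):
        status, _, _ = score_sample(calls(inversion=20, not_rearranged=29))
        assert status is FishStatus.INSUFFICIENT

    def test_three_prime_deletion_never_counts(self):
        """A sample dominated by 3'-deletion nuclei stays negative under
        the guidelines but raises the atypical flag."""
        status, pct, atypical = score_sample(
            calls(three_prime_deletion=74, inversion=4, not_rearranged=22)
        )
        assert status is FishStatus.NEGATIVE
        assert pct == pytest.approx(4.0)
        assert atypical


class TestDerivable:
    def test_sub_multiset_is_derivable(self):
        assert derivable(residue("OB"), residue("OB", "GB"))

    def test_more_complex_minority_is_not(self):
        assert not derivable(residue("OB", "GB"), residue("OB"))

    def test_whole_token_equality_only(self):
        # O is not a whole token of {OB, GB}: a co-localized spot cannot
        # shed one channel through sectioning
        assert not derivable(residue("O", "GB"), residue("OB", "GB"))

    def test_multiplicities_matter(self):
        assert not derivable(residue("OB", "OB"), residue("OB", "GB"))


class TestDerivePatternSet:
    def test_sectioning_derivative_folds_into_predominant(self):
        out = derive_pattern_set({"OB/GB": 40.0, "OB": 10.0})
        assert [c for c, _ in out] == [P.INVERSION]
        assert out[0][1] == pytest.approx(50.0)

    def test_three_independent_patterns_ordered_by_share(self):
        out = derive_pattern_set({"O": 30.0, "O/GB": 12.0, "OB/GB": 6.0})
        assert [c for c, _ in out] == [
            P.FIVE_PRIME_DELETION, P.TRANSLOCATION, P.INVERSION,
        ]

    def test_subthreshold_minority_discarded(self):
        out = derive_pattern_set({"OB/GB": 50.0, "O/GB": 3.0})
        assert [c for c, _ in out] == [P.INVERSION]

    def test_minority_cutoff_inclusive(self):
        out = derive_pattern_set({"OB/GB": 50.0, "O/GB": 4.0})
        assert [c for c, _ in out] == [P.INVERSION, P.TRANSLOCATION]

    def test_empty_input_empty_set(self):
        assert derive_pattern_set({}) == ()

    def test_fold_idempotence(self):
        """Re-deriving from a derived pattern set is a fixed point."""
        from alkfish.fish_signals import residue_label

        first = derive_pattern_set({"OB": 55.0, "OB/GB": 30.0, "O": 10.0})
        again = derive_pattern_set(
            {
                residue_label(CANONICAL_VARIANTS[cls]): pct
                for cls, pct in first
            }
        )
        assert [c for c, _ in again] == [c for c, _ in first]

    def test_adding_predominant_mass_never_changes_the_set(self):
        base = {"OB": 55.0, "OB/GB": 30.0}
        ref = [c for c, _ in derive_pattern_set(base)]
        for extra in (10.0, 40.0, 200.0):
            grown = {"OB": 55.0 + extra, "OB/GB": 30.0}
            assert [c for c, _ in derive_pattern_set(grown)] == ref

    def test_pairwise_vocabulary_matches_derivability(self):
        """For every ordered pair of canonical variants, the minority
        survives as a second pattern exactly when it is not derivable
        from the predominant — reproducing which two-pattern
        combinations can occur at all."""
        from alkfish.fish_signals import residue_label

        for a, b in itertools.permutations(CANONICAL_VARIANTS, 2):
            ra, rb = CANONICAL_VARIANTS[a], CANONICAL_VARIANTS[b]
            out = derive_pattern_set(
                {residue_label(ra): 60.0, residue_label(rb): 30.0}
            )
            got = [c for c, _ in out]
            if derivable(rb, ra):
                assert got == [a], (a, b)
            else:
                assert got == [a, b], (a, b)

    def test_reference_vocabulary_is_reachable_and_consistent(self):
        """Every combination of the reference table survives its own
        derivability check (no listed combination folds away)."""
        from alkfish.fish_signals import residue_label

        for _grp, classes, _comp, _n in reference_pattern_counts():
            pred = CANONICAL_VARIANTS[classes[0]]
            for minority_cls in classes[1:]:
                assert not derivable(CANONICAL_VARIANTS[minority_cls], pred)
            shares = {
                residue_label(CANONICAL_VARIANTS[c]): pct
                for c, pct in zip(classes, (60.0, 25.0, 10.0))
            }
            assert [c for c, _ in derive_pattern_set(shares)] == list(classes)


class TestCompositePositivity:
    def test_single_variant_reaching_cutoff(self):
        assert compose_subthreshold_positive({"OB/GB": 18.0, "O/GB": 8.0})

    def test_composite_positive(self):
        assert not compose_subthreshold_positive(
            {"O": 12.0, "O/GB": 8.0, "OB/GB": 5.0}
        )

    def test_boundary_inclusive(self):
        assert compose_subthreshold_positive({"OB/GB": 15.0})


class TestCng:
    def test_copy_number_classes(self):
        assert copy_number_category(2) == "<=3"
        assert copy_number_category(4) == "4-6"
        assert copy_number_category(9) == "7-9"
        assert copy_number_category(10) == "10+"

    def test_highest_class_reaching_theta_wins(self):
        assert categorize_cng({"4-6": 0.16, "7-9": 0.01}) == "4-6"

    def test_all_low_copy(self):
        assert categorize_cng({"<=3": 1.0}) == "<=3"

    def test_theta_sensitivity(self):
        fractions = {"4-6": 0.17, "10+": 0.08}
        assert categorize_cng(fractions, theta=0.05) == "10+"
        assert categorize_cng(fractions, theta=0.10) == "4-6"

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            categorize_cng({"4-6": -0.1})


class TestSummarizeSample:
    def test_full_sample_summary(self):
        intact = token("OG")
        nuclei = (
            [NucleusObservation((intact, *residue("OB", "GB"))) for _ in range(22)]
            + [NucleusObservation((intact, *residue("OB"))) for _ in range(4)]
            + [NucleusObservation((intact, intact)) for _ in range(74)]
        )
        res = summarize_sample(nuclei, sample_id="s1")
        assert res.status is FishStatus.POSITIVE
        assert res.n_enumerated == 100
        assert res.percent_rearranged == pytest.approx(26.0)
        assert res.pattern_classes == (P.INVERSION,)
        assert not res.composite_positive
        assert res.cng_category == "<=3"
        # variant shares of enumerated nuclei sum to the rearranged share
        assert sum(res.variant_percentages.values()) == pytest.approx(26.0)

    def test_insufficient_sample(self):
        intact = token("OG")
        nuclei = [NucleusObservation((intact, intact)) for _ in range(49)]
        res = summarize_sample(nuclei)
        assert res.status is FishStatus.INSUFFICIENT
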