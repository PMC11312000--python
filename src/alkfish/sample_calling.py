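"""Sample-level aggregation of per-nucleus ALK FISH calls.

Implements the guideline scoring rules:

* at least 50 enumerable nuclei are required (100 are read when material
  allows); below 50 the sample is ``INSUFFICIENT`` and excluded from
  cohort statistics;
* a sample is ALK-positive when >= 15% of enumerated nuclei carry a
  rearranged configuration that counts under the guidelines
  (translocation, inversion, 5' deletion, interstitial deletion);
  3'-deletion and unclassifiable configurations are recorded and raise
  the atypical flag but never enter the positive numerator;
* the positive result may come from a single variant at >= 15% of
  enumerated nuclei or be *composite* — several variants each below 15%;
* the predominant rearrangement pattern is the variant with the highest
  share of rearranged nuclei; every minority variant is kept as a
  secondary/tertiary pattern only if it reaches 4% of rearranged nuclei
  and cannot be *derived* from the predominant configuration by losing
  whole signals — otherwise it is folded in as a tissue-sectioning
  artifact;
* copy-number gain (CNG) is read off intact-fusion multiplicity per
  nucleus and reduced to one sample category (``<=3``, ``4-6``, ``7-9``,
  ``10+``) by a threshold-fraction rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .fish_signals import (
    POSITIVE_PATTERN_CLASSES,
    NucleusObservation,
    PatternClass,
    SIGNATURES_BY_RESIDUE,
    classify_nucleus_tricheck,
    extract_residue,
    residue,
    residue_label,
)

__all__ = [
    "FishStatus",
    "FishSampleResult",
    "CNG_CATEGORIES",
    "MIN_NUCLEI",
    "POSITIVITY_THRESHOLD_PCT",
    "MINORITY_THRESHOLD_PCT",
    "copy_number_category",
    "score_sample",
    "derivable",
    "derive_pattern_set",
    "compose_subthreshold_positive",
    "categorize_cng",
    "summarize_sample",
]

logger = logging.getLogger(__name__)

#: Minimum enumerable nuclei for a valid sample.
MIN_NUCLEI = 50
#: Positivity cut-off, % of enumerated nuclei (inclusive).
POSITIVITY_THRESHOLD_PCT = 15.0
#: Minority-pattern retention cut-off, % of rearranged nuclei (inclusive).
MINORITY_THRESHOLD_PCT = 4.0

#: Sample-level copy-number-gain categories, lowest to highest.
CNG_CATEGORIES = ("<=3", "4-6", "7-9", "10+")


class FishStatus(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INSUFFICIENT = "insufficient"

    def __str__(self) -> str:
        return self.value


def copy_number_category(copy_number: int) -> str:
    """Map a per-nucleus intact-fusion count to its CNG class."""
    if copy_number < 0:
        raise ValueError("copy number must be non-negative")
    if copy_number <= 3:
        return "<=3"
    if copy_number <= 6:
        return "4-6"
    if copy_number <= 9:
        return "7-9"
    return "10+"


@dataclass(frozen=True)
class FishSampleResult:
    """Sample-level FISH outcome.

    ``variant_percentages`` maps a residue label (e.g. ``"OB/GB"``) to
    its share of *enumerated* nuclei, in percent, for guideline-countable
    variants; they sum to ``percent_rearranged``.  ``pattern_set`` is the
    ordered derived pattern-class sequence (predominant class first) with
    each class's summed share of *rearranged* nuclei.
    """

    sample_id: str
    n_enumerated: int
    n_rearranged: int
    percent_rearranged: float
    variant_percentages: Mapping[str, float]
    pattern_set: tuple  # of (PatternClass, percent-of-rearranged)
    status: FishStatus
    atypical_flag: bool
    single_variant_ge_threshold: bool | None
    cng_fractions: Mapping[str, float]
    cng_category: str

    @property
    def pattern_classes(self) -> tuple:
        return tuple(cls for cls, _ in self.pattern_set)

    @property
    def composite_positive(self) -> bool:
        """Positive without any single variant reaching the 15% cut-off."""
        return (
            self.status is FishStatus.POSITIVE
            and self.single_variant_ge_threshold is False
        )


def score_sample(
    calls: Sequence[PatternClass],
    min_nuclei: int = MIN_NUCLEI,
    threshold_pct: float = POSITIVITY_THRESHOLD_PCT,
) -> tuple:
    """Score a sequence of per-nucleus calls.

    Returns ``(status, percent_rearranged, atypical_flag)``.  The
    numerator counts only guideline-positive classes; 3'-deletion and
    unclassified nuclei set the atypical flag.  Fewer than ``min_nuclei``
    calls yield ``INSUFFICIENT``.
    """
    if not calls:
        raise ValueError("no per-nucleus calls supplied")
    n = len(calls)
    n_rearranged = sum(1 for c in calls if c in POSITIVE_PATTERN_CLASSES)
    atypical = any(
        c in (PatternClass.THREE_PRIME_DELETION, PatternClass.UNCLASSIFIED)
        for c in calls
    )
    pct = 100.0 * n_rearranged / n
    if n < min_nuclei:
        return FishStatus.INSUFFICIENT, pct, atypical
    status = FishStatus.POSITIVE if pct >= threshold_pct else FishStatus.NEGATIVE
    return status, pct, atypical


def derivable(minority_residue: Iterable, predominant_residue: Iterable) -> bool:
    """Can the minority configuration arise from the predominant one by
    whole-signal loss (tissue sectioning)?

    True iff the minority residue is a sub-multiset of the predominant
    residue under exact token equality.  Sectioning truncates a nucleus
    and removes whole signals; it never strips one channel out of a
    co-localized spot, so token identity is preserved.
    """
    minority = Counter(minority_residue)
    predominant = Counter(predominant_residue)
    return all(predominant[t] >= k for t, k in minority.items())


def _parse_label(label: str) -> tuple:
    return residue(*label.split("/"))


def derive_pattern_set(
    variant_percentages: Mapping[str, float],
    minority_threshold_pct: float = MINORITY_THRESHOLD_PCT,
    max_patterns: int = 3,
) -> tuple:
    """Derive the ordered pattern-class set of a positive sample.

    Parameters
    ----------
    variant_percentages
        Residue label -> percent of *rearranged* nuclei, for
        guideline-countable variants only.
    minority_threshold_pct
        Minimum share of rearranged nuclei for a minority variant to be
        retained as an independent pattern (inclusive).

    Returns
    -------
    tuple of (PatternClass, percent)
        Classes ordered by summed share of rearranged nuclei
        (descending), truncated at ``max_patterns``.  Variants derivable
        from the predominant configuration are folded into the
        predominant's class; sub-threshold non-derivable variants are
        discarded (logged).  Empty input -> empty tuple.
    """
    items = [
        (label, _parse_label(label), pct)
        for label, pct in variant_percentages.items()
        if pct > 0
    ]
    if not items:
        return ()
    # predominant variant: highest share; ties go to the residue with
    # more signals, then lexicographically smallest label (logged: the
    # guideline never defines this case).
    items.sort(key=lambda it: (-it[2], -len(it[1]), it[0]))
    if len(items) > 1 and items[0][2] == items[1][2]:
        logger.info(
            "predominant-variant tie between %s and %s; resolved by token "
            "count then label", items[0][0], items[1][0],
        )
    pred_label, pred_residue, _ = items[0]
    pred_class = SIGNATURES_BY_RESIDUE[pred_residue].pattern_class

    class_pct: dict = {}
    for label, res, pct in items:
        if label == pred_label or derivable(res, pred_residue):
            # the predominant variant itself, or a sectioning derivative
            if label != pred_label:
                logger.debug(
                    "variant %s (%.1f%%) folded into predominant %s as a "
                    "sectioning artifact", label, pct, pred_label,
                )
            class_pct[pred_class] = class_pct.get(pred_class, 0.0) + pct
        elif pct >= minority_threshold_pct:
            cls = SIGNATURES_BY_RESIDUE[res].pattern_class
            class_pct[cls] = class_pct.get(cls, 0.0) + pct
        else:
            logger.debug(
                "variant %s (%.1f%%) below the %.0f%% minority cut-off; "
                "discarded", label, pct, minority_threshold_pct,
            )

    ordered = sorted(class_pct.items(), key=lambda kv: (-kv[1], kv[0].value))
    if len(ordered) > max_patterns:
        logger.warning(
            "pattern set truncated from %d to %d classes; dropped: %s",
            len(ordered),
            max_patterns,
            [(str(c), round(p, 2)) for c, p in ordered[max_patterns:]],
        )
        ordered = ordered[:max_patterns]
    return tuple(ordered)


def compose_subthreshold_positive(
    variant_percentages_enumerated: Mapping[str, float],
    threshold_pct: float = POSITIVITY_THRESHOLD_PCT,
) -> bool:
    """Does any single variant reach the positivity cut-off on its own?

    Input percentages are shares of *enumerated* nuclei.  ``False`` on a
    positive sample means the result is *composite*: assembled from
    several variants each below the cut-off.
    """
    return any(p >= threshold_pct for p in variant_percentages_enumerated.values())


def categorize_cng(
    cng_fractions: Mapping[str, float], theta: float = 0.10
) -> str:
    """Reduce per-nucleus CNG fractions to one sample category.

    ``cng_fractions`` maps CNG class to the fraction of nuclei in that
    class.  The sample category is the highest class whose fraction
    reaches ``theta``; with no elevated class above threshold the sample
    is ``"<=3"``.
    """
    total = 0.0
    for cls, frac in cng_fractions.items():
        if cls not in CNG_CATEGORIES:
            raise ValueError(f"unknown CNG class {cls!r}")
        if frac < 0:
            raise ValueError(f"negative fraction for CNG class {cls!r}")
        total += frac
    if total > 1.0 + 1e-9:
        raise ValueError("CNG fractions sum to more than 1")
    for cls in ("10+", "7-9", "4-6"):
        if cng_fractions.get(cls, 0.0) >= theta:
            return cls
    return "<=3"


def summarize_sample(
    nuclei: Sequence[NucleusObservation],
    sample_id: str = "",
    theta_cng: float = 0.10,
    min_nuclei: int = MIN_NUCLEI,
) -> FishSampleResult:
    """Run the full per-sample tri-colour scoring pipeline.

    Classifies every enumerable nucleus, applies the positivity rule,
    derives the pattern set for positive samples and reduces the CNG
    profile to one category.
    """
    enumerable = [n for n in nuclei if n.tokens]
    if not enumerable:
        raise ValueError(f"sample {sample_id!r} has no enumerable nuclei")

    calls = []
    variant_counts: Counter = Counter()
    cng_counts: Counter = Counter()
    for nuc in enumerable:
        cls = classify_nucleus_tricheck(nuc)
        calls.append(cls)
        cng_counts[copy_number_category(nuc.copy_number)] += 1
        if cls in POSITIVE_PATTERN_CLASSES:
            variant_counts[residue_label(extract_residue(nuc))] += 1

    n = len(enumerable)
    status, pct_rearranged, atypical = score_sample(calls, min_nuclei=min_nuclei)
    n_rearranged = sum(variant_counts.values())
    variant_pct = {lbl: 100.0 * c / n for lbl, c in sorted(variant_counts.items())}
    cng_fractions = {cls: cng_counts.get(cls, 0) / n for cls in CNG_CATEGORIES}

    pattern_set: tuple = ()
    single_ge = None
    if status is FishStatus.POSITIVE:
        of_rearranged = {
            lbl: 100.0 * c / n_rearranged for lbl, c in variant_counts.items()
        }
        pattern_set = derive_pattern_set(of_rearranged)
        single_ge = compose_subthreshold_positive(variant_pct)

    return FishSampleResult(
        sample_id=sample_id,
        n_enumerated=n,
        n_rearranged=n_rearranged,
        percent_rearranged=pct_rearranged,
        variant_percentages=variant_pct,
        pattern_set=pattern_set,
        status=status,
        atypical_flag=atypical,
        single_variant_ge_threshold=single_ge,
        cng_fractions=cng_fractions,
        cng_category=categorize_cng(cng_fractions, theta=theta_cng),
    )
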