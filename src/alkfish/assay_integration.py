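"""IHC scoring, NGS gating, and IHC/FISH concordance classification.

The diagnostic setting: every case is tested in parallel by ALK
immunohistochemistry (D5F3 antibody, semiquantitative staining
categories) and ALK FISH; a subset is additionally sequenced on a
DNA+RNA panel.  Cases divide into four concordance classes —
positive/negative x concordant/discordant — with FISH+/IHC- cases
("positive discordant") eligible for an IHC repeat in which focal
*dot-like* staining is accepted as positive and moves the case to
positive concordant.

Sensitivity and specificity of FISH are computed against protein
expression as the reference: sensitivity = pos_conc / (pos_conc +
neg_disc); specificity = neg_conc / (neg_conc + pos_disc).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .sample_calling import FishSampleResult, FishStatus

__all__ = [
    "IhcStaining",
    "IhcObservation",
    "IhcStatus",
    "Concordance",
    "ConcordanceCounts",
    "NgsSample",
    "FusionEvidence",
    "QcResult",
    "CaseRecord",
    "score_ihc",
    "classify_concordance",
    "apply_reevaluation",
    "ngs_qc",
    "call_ngs_fusion",
    "sensitivity_specificity",
    "cohort_summaries",
    "CohortSummary",
    "round_pct",
]

#: Minimum unique supporting reads for a high-confidence fusion call.
MIN_FUSION_READS = 5


class IhcStaining(Enum):
    """Semiquantitative ALK IHC staining categories."""

    NONE = "none"
    WEAK_1PLUS = "weak_1plus"
    STRONG_2PLUS = "strong_2plus"
    STRONG_3PLUS = "strong_3plus"
    DOT_LIKE = "dot_like"
    STIPPLED = "stippled"

    def __str__(self) -> str:
        return self.value


class IhcStatus(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class IhcObservation:
    """One IHC read-out: exactly one staining category, plus whether it
    comes from the reevaluation (repeat) stage, where dot-like staining
    counts as positive."""

    staining: IhcStaining
    is_reevaluation: bool = False


def score_ihc(obs: IhcObservation) -> IhcStatus:
    """Binary IHC status.

    Strong diffuse granular cytoplasmic staining (2+, 3+) is positive;
    dot-like staining is positive only at the reevaluation stage.  No
    staining, weak (1+) and stippled staining are negative.
    """
    positive = obs.staining in (IhcStaining.STRONG_2PLUS, IhcStaining.STRONG_3PLUS)
    if obs.staining is IhcStaining.DOT_LIKE and obs.is_reevaluation:
        positive = True
    return IhcStatus.POSITIVE if positive else IhcStatus.NEGATIVE


class Concordance(Enum):
    POS_CONC = "positive_concordant"
    NEG_CONC = "negative_concordant"
    POS_DISC = "positive_discordant"  # FISH+, IHC-
    NEG_DISC = "negative_discordant"  # FISH-, IHC+
    EXCLUDED = "excluded"

    def __str__(self) -> str:
        return self.value


def classify_concordance(ihc: IhcStatus, fish: FishStatus) -> Concordance:
    """Four-way concordance class; INSUFFICIENT FISH propagates as
    EXCLUDED, never as a concordance class."""
    if fish is FishStatus.INSUFFICIENT:
        return Concordance.EXCLUDED
    fish_pos = fish is FishStatus.POSITIVE
    ihc_pos = ihc is IhcStatus.POSITIVE
    if fish_pos and ihc_pos:
        return Concordance.POS_CONC
    if fish_pos:
        return Concordance.POS_DISC
    if ihc_pos:
        return Concordance.NEG_DISC
    return Concordance.NEG_CONC


@dataclass(frozen=True)
class ConcordanceCounts:
    """Cohort-level concordance class counts."""

    pos_conc: int
    pos_disc: int
    neg_disc: int
    neg_conc: int

    def __post_init__(self) -> None:
        for name in ("pos_conc", "pos_disc", "neg_disc", "neg_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.pos_conc + self.pos_disc + self.neg_disc + self.neg_conc

    @property
    def fish_positive(self) -> int:
        return self.pos_conc + self.pos_disc

    @property
    def fish_negative(self) -> int:
        return self.neg_conc + self.neg_disc


def apply_reevaluation(
    counts: ConcordanceCounts, repeat_results: Sequence[IhcObservation]
) -> ConcordanceCounts:
    """Fold IHC repeat results for positive-discordant cases back into
    the cohort counts.

    Each repeat observation scoring positive (in practice: dot-like
    staining at reevaluation) moves one case POS_DISC -> POS_CONC; a
    still-negative repeat leaves the case discordant.  The total case
    count is conserved.
    """
    if len(repeat_results) > counts.pos_disc:
        raise ValueError(
            f"{len(repeat_results)} repeat results for only "
            f"{counts.pos_disc} positive-discordant cases"
        )
    for obs in repeat_results:
        if not obs.is_reevaluation:
            raise ValueError("repeat results must be flagged is_reevaluation")
    n_moved = sum(
        1 for obs in repeat_results if score_ihc(obs) is IhcStatus.POSITIVE
    )
    return replace(
        counts,
        pos_conc=counts.pos_conc + n_moved,
        pos_disc=counts.pos_disc - n_moved,
    )


@dataclass(frozen=True)
class FusionEvidence:
    """One candidate fusion from the RNA panel."""

    partner_gene: str
    unique_reads: int
    driver_gene: str = "ALK"

    @property
    def involves_alk(self) -> bool:
        return "ALK" in (self.driver_gene, self.partner_gene)


@dataclass(frozen=True)
class NgsSample:
    """Panel-sequencing input metrics and raw evidence for one case.

    ``dv200`` is the percentage of RNA fragments longer than 200 bp (the
    RNA-degradation gate); ``tumor_content`` is the tumour-cell fraction
    of the specimen.
    """

    dna_ng: Optional[float] = None
    rna_conc: Optional[float] = None       # ng/uL
    dv200: Optional[float] = None          # %
    library_conc: Optional[float] = None   # ng/uL
    tumor_content: Optional[float] = None  # fraction
    fusion_evidence: tuple = ()
    cnv_evidence: tuple = ()               # of (gene, copy_count)

    def __post_init__(self) -> None:
        if self.dv200 is not None and not 0 <= self.dv200 <= 100:
            raise ValueError("dv200 must be a percentage in [0, 100]")
        if self.tumor_content is not None and not 0 <= self.tumor_content <= 1:
            raise ValueError("tumor_content must be a fraction in [0, 1]")
        for ev in self.fusion_evidence:
            if ev.unique_reads < 0:
                raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.passed


# (field, threshold, inclusive, failure reason) in gating order; the DNA
# input floor is inclusive ("minimal required amount"), the RNA, DV200
# and library gates are strict.
_QC_GATES = (
    ("dna_ng", 80.0, True, "dna_insufficient"),
    ("rna_conc", 10.0, False, "rna_low_concentration"),
    ("dv200", 30.0, False, "rna_degraded"),
    ("library_conc", 3.0, False, "library_low_concentration"),
    ("tumor_content", 0.20, False, "low_tumor_content"),
)


def ngs_qc(sample: NgsSample) -> QcResult:
    """Sequencing input gates; fail carries the first violated criterion."""
    for field_name, threshold, inclusive, reason in _QC_GATES:
        value = getattr(sample, field_name)
        if value is None:
            return QcResult(False, "missing_data")
        ok = value >= threshold if inclusive else value > threshold
        if not ok:
            return QcResult(False, reason)
    return QcResult(True)


def call_ngs_fusion(
    fusion_evidence: Iterable, min_unique_reads: int = MIN_FUSION_READS
) -> tuple:
    """High-confidence fusion calls: at least ``min_unique_reads`` unique
    supporting reads."""
    return tuple(ev for ev in fusion_evidence if ev.unique_reads >= min_unique_reads)


def round_pct(x: float, ndigits: int = 1) -> float:
    """Percentage rounding used in reports (round-half-even)."""
    return round(x, ndigits)


def sensitivity_specificity(counts: ConcordanceCounts) -> tuple:
    """FISH sensitivity and specificity against protein expression.

    Returns ``(sensitivity_pct, specificity_pct)`` rounded to one
    decimal; a zero denominator yields ``None`` for that metric.
    """
    sens_den = counts.pos_conc + counts.neg_disc
    spec_den = counts.neg_conc + counts.pos_disc
    sens = round_pct(100.0 * counts.pos_conc / sens_den) if sens_den else None
    spec = round_pct(100.0 * counts.neg_conc / spec_den) if spec_den else None
    return sens, spec


@dataclass(frozen=True)
class CohortSummary:
    """Headline concordance rates of a cohort, in percent."""

    counts: ConcordanceCounts
    discordant_pct: float
    pos_disc_pct: float
    neg_disc_pct: float
    pos_disc_of_fish_positive_pct: Optional[float]
    neg_disc_of_fish_negative_pct: Optional[float]
    sensitivity_pct: Optional[float]
    specificity_pct: Optional[float]


def cohort_summaries(counts: ConcordanceCounts) -> CohortSummary:
    """Discordance rates and FISH accuracy metrics for a cohort.

    An empty cohort yields undefined (``None``) markers for every rate.
    """
    n = counts.total
    if n == 0:
        return CohortSummary(counts, None, None, None, None, None, None, None)
    disc = counts.pos_disc + counts.neg_disc
    sens, spec = sensitivity_specificity(counts)
    return CohortSummary(
        counts=counts,
        discordant_pct=round_pct(100.0 * disc / n, 2),
        pos_disc_pct=round_pct(100.0 * counts.pos_disc / n, 2),
        neg_disc_pct=round_pct(100.0 * counts.neg_disc / n, 2),
        pos_disc_of_fish_positive_pct=(
            round_pct(100.0 * counts.pos_disc / counts.fish_positive)
            if counts.fish_positive
            else None
        ),
        neg_disc_of_fish_negative_pct=(
            round_pct(100.0 * counts.neg_disc / counts.fish_negative)
            if counts.fish_negative
            else None
        ),
        sensitivity_pct=sens,
        specificity_pct=spec,
    )


@dataclass(frozen=True)
class CaseRecord:
    """One tumour case with its assay results and concordance class."""

    case_id: str
    age: Optional[int] = None
    sex: Optional[str] = None  # "M" / "F"
    histology: Optional[str] = None
    ihc: Optional[IhcObservation] = None
    ihc_repeat: Optional[IhcObservation] = None
    fish: Optional[FishSampleResult] = None
    ngs: Optional[NgsSample] = None

    @property
    def ihc_status(self) -> Optional[IhcStatus]:
        if self.ihc is None:
            return None
        status = score_ihc(self.ihc)
        if (
            status is IhcStatus.NEGATIVE
            and self.ihc_repeat is not None
        ):
            return score_ihc(self.ihc_repeat)
        return status

    @property
    def concordance(self) -> Optional[Concordance]:
        if self.ihc is None or self.fish is None:
            return None
        return classify_concordance(self.ihc_status, self.fish.status)
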