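"""Domain types and per-nucleus classification rules for ALK FISH probes.

Two probe designs are modelled:

* the dual-colour *break-apart* probe, whose 3' (orange) and 5' (green)
  arms flank the ALK breakpoint — separation of the two arms, or loss of
  the 5' arm, marks a rearranged locus;
* the tri-colour *ALK/EML4 fusion* probe, which adds a blue EML4 arm and
  therefore distinguishes the canonical intrachromosomal ALK::EML4
  inversion from translocations with other partners and from partial
  deletions.

A nucleus is encoded as a multiset of :class:`SignalToken`; each token is
the non-empty set of fluorescence channels observed co-localized at one
spot.  A token carrying both the orange 3' and green 5' channel is an
*intact fusion* signal (an unrearranged ALK locus); the per-nucleus count
of intact fusions is the ALK copy number.  Classification removes intact
fusions and matches the residual tokens against a shipped signature table
of rearrangement variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ORANGE_3P",
    "GREEN_5P",
    "BLUE",
    "SignalToken",
    "NucleusObservation",
    "PatternClass",
    "POSITIVE_PATTERN_CLASSES",
    "BreakApartCall",
    "VariantSignature",
    "SIGNATURE_TABLE",
    "SIGNATURES_BY_RESIDUE",
    "UnenumerableNucleusError",
    "token",
    "residue",
    "residue_label",
    "extract_residue",
    "classify_nucleus_tricheck",
    "classify_nucleus_breakapart",
    "erase_blue",
]

# Channel codes.  Single letters are used throughout file formats and
# variant labels; the long names document the probe arm each represents.
ORANGE_3P = "O"  # 3' ALK arm (orange)
GREEN_5P = "G"   # 5' ALK arm (green)
BLUE = "B"       # EML4 arm (blue)

_CHANNEL_ORDER = {ORANGE_3P: 0, GREEN_5P: 1, BLUE: 2}
_VALID_CHANNELS = frozenset(_CHANNEL_ORDER)


@dataclass(frozen=True)
class SignalToken:
    """One fluorescence spot: the non-empty set of co-localized channels."""

    channels: frozenset

    def __post_init__(self) -> None:
        channels = frozenset(self.channels)
        if not channels:
            raise ValueError("a signal token must carry at least one channel")
        unknown = channels - _VALID_CHANNELS
        if unknown:
            raise ValueError(f"unknown channel code(s): {sorted(unknown)}")
        object.__setattr__(self, "channels", channels)

    @property
    def is_intact_fusion(self) -> bool:
        """True for a co-localized orange/green signal (intact ALK locus)."""
        return ORANGE_3P in self.channels and GREEN_5P in self.channels

    @property
    def label(self) -> str:
        """Compact label, channels in O, G, B order (e.g. ``OB``)."""
        return "".join(sorted(self.channels, key=_CHANNEL_ORDER.__getitem__))

    def __lt__(self, other: "SignalToken") -> bool:
        return self.sort_key < other.sort_key

    @property
    def sort_key(self) -> tuple:
        # canonical channel order, so labels read O / OB / GB / B …
        return tuple(sorted(_CHANNEL_ORDER[c] for c in self.channels))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SignalToken({self.label!r})"


def token(code: str) -> SignalToken:
    """Parse a token code such as ``"O+G"``, ``"OG"`` or ``"b"``."""
    letters = code.replace("+", "").strip().upper()
    if not letters:
        raise ValueError("empty signal token")
    return SignalToken(frozenset(letters))


def residue(*codes: str) -> tuple:
    """Build a canonical (sorted) token multiset from compact codes."""
    return tuple(sorted(token(c) for c in codes))


def residue_label(tokens: Iterable[SignalToken]) -> str:
    """Canonical label of a token multiset, e.g. ``"OB/GB"``."""
    return "/".join(t.label for t in sorted(tokens))


class PatternClass(Enum):
    """Rearrangement pattern classes assignable to one nucleus.

    ``THREE_PRIME_DELETION`` (loss of the 3' orange arm with retained 5'
    green signal) and ``UNCLASSIFIED`` configurations are recorded and
    flagged but never count toward ALK positivity under the scoring
    guidelines.
    """

    TRANSLOCATION = "translocation"
    INVERSION = "inversion"
    FIVE_PRIME_DELETION = "five_prime_deletion"
    INTERSTITIAL_DELETION = "interstitial_deletion"
    THREE_PRIME_DELETION = "three_prime_deletion"
    UNCLASSIFIED = "unclassified"
    NOT_REARRANGED = "not_rearranged"

    def __str__(self) -> str:
        return self.value


#: Classes that count toward the ALK-positive numerator.
POSITIVE_PATTERN_CLASSES = frozenset(
    {
        PatternClass.TRANSLOCATION,
        PatternClass.INVERSION,
        PatternClass.FIVE_PRIME_DELETION,
        PatternClass.INTERSTITIAL_DELETION,
    }
)


class BreakApartCall(Enum):
    """Per-nucleus call under the dual-colour break-apart probe."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    #: isolated orange/green pair separated by less than two signal
    #: diameters; scored negative but flagged for tri-colour retesting
    SHORT_BREAK = "short_break"


class UnenumerableNucleusError(ValueError):
    """Raised for a nucleus with no signals: recorded but never counted."""


@dataclass(frozen=True)
class NucleusObservation:
    """Signals observed in one tumour nucleus.

    Parameters
    ----------
    tokens
        Multiset of signal tokens (stored canonically sorted).
    split_distance_ok
        For break-apart scoring: ``True`` iff every isolated orange/green
        pair is separated by at least two signal diameters.  ``None`` when
        no pair distance applies (tri-colour input).  Distances are
        measured upstream; this is an input flag, never recomputed here.
    nucleus_id
        Opaque identifier.
    """

    tokens: tuple
    split_distance_ok: bool | None = None
    nucleus_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(sorted(self.tokens)))

    @property
    def copy_number(self) -> int:
        """Number of intact fusion signals = ALK copy number."""
        return sum(1 for t in self.tokens if t.is_intact_fusion)


@dataclass(frozen=True)
class VariantSignature:
    """One rearrangement variant: a residual signal configuration.

    ``residue`` is the nucleus's token multiset after removal of all
    intact fusion tokens; matching is by exact multiset equality, so
    multiplicities matter (``OB`` and ``OB/OB`` are distinct residues).
    """

    residue: tuple
    pattern_class: PatternClass
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue", tuple(sorted(self.residue)))
        if not self.label:
            object.__setattr__(self, "label", residue_label(self.residue))


def _build_signature_table() -> tuple:
    spec: list[tuple[PatternClass, list[tuple]]] = [
        # Translocation with a partner other than EML4: the 5' green arm
        # leaves the ALK locus without acquiring the blue EML4 channel.
        (
            PatternClass.TRANSLOCATION,
            [residue("O", "GB"), residue("O", "G"), residue("O", "G", "B")],
        ),
        # ALK::EML4 inversion: the split arms co-localize with blue.
        (
            PatternClass.INVERSION,
            [
                residue("OB", "GB"),
                residue("OB", "G"),
                residue("OB", "B", "G"),
                residue("OB", "B"),  # inversion with partial ALK deletion
            ],
        ),
        # 5' deletion: isolated 3' orange, green arm lost.
        (
            PatternClass.FIVE_PRIME_DELETION,
            [residue("O"), residue("O", "B")],
        ),
        # Interstitial deletion: isolated 3' orange co-localized with blue.
        (
            PatternClass.INTERSTITIAL_DELETION,
            [residue("OB")],
        ),
        # 3' deletion: 5' green retained (with blue), orange arm lost.
        # Flagged-only; never counts toward positivity under guidelines.
        (
            PatternClass.THREE_PRIME_DELETION,
            [residue("GB"), residue("GB", "B"), residue("GB", "GB", "B")],
        ),
    ]
    table = []
    for cls, residues in spec:
        for res in residues:
            table.append(VariantSignature(res, cls))
    return tuple(table)


#: The shipped variant signature table (total and unambiguous).
SIGNATURE_TABLE: tuple = _build_signature_table()

#: Lookup from canonical residue multiset to its signature.
SIGNATURES_BY_RESIDUE: Mapping[tuple, VariantSignature] = {
    sig.residue: sig for sig in SIGNATURE_TABLE
}

if len(SIGNATURES_BY_RESIDUE) != len(SIGNATURE_TABLE):  # pragma: no cover
    raise AssertionError("signature table is ambiguous")


def extract_residue(nucleus: NucleusObservation) -> tuple:
    """Remove all intact fusion tokens; return the residual multiset.

    The number of removed tokens is the nucleus's ALK copy number,
    available separately as :attr:`NucleusObservation.copy_number`.

    Raises
    ------
    UnenumerableNucleusError
        If the nucleus carries no signals at all.
    """
    if not nucleus.tokens:
        raise UnenumerableNucleusError(
            f"nucleus {nucleus.nucleus_id!r} has no signals and cannot be enumerated"
        )
    return tuple(t for t in nucleus.tokens if not t.is_intact_fusion)


def classify_nucleus_tricheck(
    nucleus: NucleusObservation,
    table: Mapping[tuple, VariantSignature] = SIGNATURES_BY_RESIDUE,
) -> PatternClass:
    """Classify one nucleus under the tri-colour ALK/EML4 fusion probe.

    The residue (tokens minus intact fusions) is matched against the
    signature table by exact multiset equality.  An empty residue is
    ``NOT_REARRANGED``; a non-empty residue absent from the table is
    ``UNCLASSIFIED`` (the raw residue stays available via
    :func:`extract_residue` for reporting).
    """
    res = extract_residue(nucleus)
    if not res:
        return PatternClass.NOT_REARRANGED
    sig = table.get(tuple(sorted(res)))
    if sig is None:
        return PatternClass.UNCLASSIFIED
    return sig.pattern_class


def _isolated(tokens: Sequence[SignalToken], channel: str) -> int:
    """Count tokens whose ALK-channel content is exactly {channel}."""
    n = 0
    for t in tokens:
        alk = t.channels & {ORANGE_3P, GREEN_5P}
        if alk == {channel}:
            n += 1
    return n


def classify_nucleus_breakapart(nucleus: NucleusObservation) -> BreakApartCall:
    """Classify one nucleus under the dual-colour break-apart probe.

    Positive: an isolated 3' orange and isolated 5' green signal at least
    two signal diameters apart (``split_distance_ok``), and/or a single
    isolated 3' orange with no isolated green (5'-deletion pattern).  An
    orange/green pair closer than two diameters is a *short break*:
    scored negative but flagged for tri-colour retesting.
    """
    if not nucleus.tokens:
        raise UnenumerableNucleusError(
            f"nucleus {nucleus.nucleus_id!r} has no signals and cannot be enumerated"
        )
    n_orange = _isolated(nucleus.tokens, ORANGE_3P)
    n_green = _isolated(nucleus.tokens, GREEN_5P)
    if n_orange and n_green:
        if nucleus.split_distance_ok:
            return BreakApartCall.POSITIVE
        return BreakApartCall.SHORT_BREAK
    if n_orange:
        return BreakApartCall.POSITIVE
    return BreakApartCall.NEGATIVE


def erase_blue(nucleus: NucleusObservation) -> NucleusObservation:
    """Re-encode a tri-colour observation for the break-apart probe.

    The break-apart probe carries no EML4 arm: the blue channel is
    dropped from every token and tokens that become empty are removed.
    Co-localization of the remaining channels is preserved.
    """
    kept = []
    for t in nucleus.tokens:
        ch = t.channels - {BLUE}
        if ch:
            kept.append(SignalToken(frozenset(ch)))
    return NucleusObservation(
        tokens=tuple(kept),
        split_distance_ok=nucleus.split_distance_ok,
        nucleus_id=nucleus.nucleus_id,
    )
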