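"""Seeded generator of synthetic ALK FISH cohorts.

Two generation modes are provided.

:func:`realize_pattern_sample` renders a sample with *fixed* variant
counts chosen to realize a given pattern-class combination under the
scoring rules (predominant variant first, minority variants above the 4%
retention cut-off, composite samples with every variant below the 15%
positivity cut-off).  :func:`realize_reference_pattern_cohort` applies
this to the shipped reference table of combination counts, reproducing
the reference cohort's pattern-distribution structure sample by sample.

:func:`generate_cohort` draws full stochastic cohorts: per case
archetype (positive/negative x concordant/discordant) it samples a true
pattern combination, a rearranged fraction, a copy-number-gain profile,
an IHC staining category and optional sequencing fields, then renders
every nucleus as intact-fusion tokens plus the residue of its drawn
variant, passing each nucleus through a sectioning-artifact process that
deletes one whole signal with a configurable probability — the process
the pattern-folding rule exists to undo.

Randomness is counter-split: one global seed expands to one independent
stream per case keyed by (archetype index, case index), so a cohort is
byte-stable under changes to other archetypes' case counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .assay_integration import IhcStaining
from .fish_signals import (
    NucleusObservation,
    PatternClass,
    SignalToken,
    residue,
    residue_label,
    token,
)
from .sample_calling import CNG_CATEGORIES

__all__ = [
    "CANONICAL_VARIANTS",
    "ArchetypeConfig",
    "CohortConfig",
    "SyntheticCase",
    "CohortBundle",
    "realize_pattern_sample",
    "realize_reference_pattern_cohort",
    "reference_pattern_counts",
    "generate_case",
    "generate_cohort",
    "default_config",
]

#: Canonical residue realizing each countable pattern class.
CANONICAL_VARIANTS: Mapping[PatternClass, tuple] = {
    PatternClass.INVERSION: residue("OB", "GB"),
    PatternClass.TRANSLOCATION: residue("O", "GB"),
    PatternClass.FIVE_PRIME_DELETION: residue("O"),
    PatternClass.INTERSTITIAL_DELETION: residue("OB"),
}

_INTACT = token("OG")

# Fixed per-variant nucleus counts (out of 100) realizing a combination;
# chosen so the predominant variant leads, every minority variant clears
# the 4% retention cut-off, and composite recipes keep each variant below
# the 15% positivity cut-off while their sum exceeds it.
_THRESHOLD_COUNTS = {1: (30,), 2: (20, 8), 3: (20, 10, 6)}
_SUBTHRESHOLD_COUNTS = {1: (12,), 2: (12, 6), 3: (9, 7, 5)}


def _sectioned(res: tuple) -> Optional[tuple]:
    """A guideline-countable residue obtainable from ``res`` by losing
    one whole signal, or None if no deletion leaves one.

    Used to carry a composite sample's artifact mass: the derivative must
    itself count toward positivity (a 3'-deletion-like remnant would not
    enter the rearranged pool at all).
    """
    from .fish_signals import POSITIVE_PATTERN_CLASSES, SIGNATURES_BY_RESIDUE

    for i in range(len(res)):
        cand = res[:i] + res[i + 1:]
        sig = SIGNATURES_BY_RESIDUE.get(cand)
        if sig is not None and sig.pattern_class in POSITIVE_PATTERN_CLASSES:
            return cand
    return None


def realize_pattern_sample(
    classes: Sequence[PatternClass],
    composite: bool,
    rng: np.random.Generator,
    sample_id: str = "",
    n_nuclei: int = 100,
) -> list:
    """Render one sample whose derived pattern set is ``classes``.

    ``composite`` selects the recipe in which no single variant reaches
    the 15% cut-off (the positive call is assembled from subthreshold
    variants).  For a composite single-class sample the minority mass is
    carried by the sectioning derivative of the class's canonical
    residue, which the folding rule re-absorbs.  The random generator
    only shuffles nucleus order.
    """
    classes = tuple(classes)
    if not 1 <= len(classes) <= 3:
        raise ValueError("a sample realizes one to three pattern classes")
    counts = (_SUBTHRESHOLD_COUNTS if composite else _THRESHOLD_COUNTS)[len(classes)]
    variants: list = []  # (residue, n_nuclei)
    for cls, k in zip(classes, counts):
        variants.append((CANONICAL_VARIANTS[cls], k))
    if composite and len(classes) == 1:
        artifact = _sectioned(CANONICAL_VARIANTS[classes[0]])
        if artifact is None:
            raise ValueError(
                f"composite single-pattern sample of {classes[0]} cannot be "
                "realized: its residue has no sectioning derivative"
            )
        variants.append((artifact, 9))

    nuclei = []
    i = 0
    for res, k in variants:
        for _ in range(k):
            nuclei.append(
                NucleusObservation(tokens=(_INTACT,) + tuple(res), nucleus_id=str(i))
            )
            i += 1
    while i < n_nuclei:
        nuclei.append(
            NucleusObservation(tokens=(_INTACT, _INTACT), nucleus_id=str(i))
        )
        i += 1
    order = rng.permutation(len(nuclei))
    return [
        replace(nuclei[j], nucleus_id=f"{sample_id}:{k}" if sample_id else str(k))
        for k, j in enumerate(order)
    ]


_CLASS_BY_NAME = {c.value: c for c in PatternClass}


def _parse_combination(text: str) -> tuple:
    return tuple(_CLASS_BY_NAME[name] for name in text.split("+"))


def reference_pattern_counts() -> list:
    """The shipped reference combination-count table.

    Returns rows ``(cohort, classes, composite, count)`` with cohort in
    {"discordant", "concordant"} and classes a predominant-first tuple of
    :class:`PatternClass`.
    """
    path = resources.files("alkfish.data") / "pattern_combinations.tsv"
    rows = []
    with path.open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for rec in reader:
            classes = _parse_combination(rec["combination"])
            for col, composite in (("subthreshold", True), ("threshold", False)):
                n = int(rec[col])
                if n:
                    rows.append((rec["cohort"], classes, composite, n))
    return rows


def realize_reference_pattern_cohort(seed: int, n_nuclei: int = 100) -> list:
    """Render one synthetic sample per reference-cohort sample.

    Returns a list of ``(sample_id, cohort, classes, composite, nuclei)``
    covering every combination row of the reference table at its counted
    multiplicity (29 discordant + 168 concordant samples).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    out = []
    i = 0
    for cohort, classes, composite, count in reference_pattern_counts():
        for _ in range(count):
            sid = f"{cohort[:4]}-{i:03d}"
            nuclei = realize_pattern_sample(
                classes, composite, rng, sample_id=sid, n_nuclei=n_nuclei
            )
            out.append((sid, cohort, classes, composite, nuclei))
            i += 1
    return out


# --------------------------------------------------------------------------
# stochastic cohort generation


@dataclass(frozen=True)
class ArchetypeConfig:
    """Generative parameters for one case archetype.

    ``combination_weights`` maps ``(classes, composite)`` to a
    probability; it is ignored for FISH-negative archetypes, whose
    rearranged fraction stays below the positivity cut-off.
    ``rearranged_mean``/``rearranged_conc`` parameterize the Beta
    distribution of the true rearranged fraction; ``mixture_weights``
    split rearranged nuclei across the drawn combination's classes
    (predominant first).  ``sectioning_rate`` is the per-nucleus
    probability of losing one whole signal to sectioning.
    """

    name: str
    n_cases: int
    fish_positive: bool
    rearranged_mean: float
    rearranged_conc: float
    sectioning_rate: float
    cng_weights: Mapping[str, float]
    ihc_weights: Mapping[IhcStaining, float]
    combination_weights: Mapping[tuple, float] = field(default_factory=dict)
    mixture_weights: tuple = (0.65, 0.25, 0.10)
    dot_like_on_repeat: float = 0.0
    ngs_rate: float = 0.0
    ngs_partner_weights: Mapping[str, float] = field(default_factory=dict)
    female_rate: float = 0.36

    def __post_init__(self) -> None:
        if not 0 <= self.sectioning_rate <= 1:
            raise ValueError("sectioning_rate must be in [0, 1]")
        if not 0 < self.rearranged_mean < 1:
            raise ValueError("rearranged_mean must be in (0, 1)")
        for probs, what in (
            (self.cng_weights.values(), "cng_weights"),
            (self.ihc_weights.values(), "ihc_weights"),
        ):
            probs = list(probs)
            if probs and abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{what} must sum to 1")
        if self.fish_positive:
            w = list(self.combination_weights.values())
            if not w:
                raise ValueError(
                    f"FISH-positive archetype {self.name!r} needs combination_weights"
                )
            if abs(sum(w) - 1.0) > 1e-6:
                raise ValueError("combination_weights must sum to 1")


@dataclass(frozen=True)
class CohortConfig:
    """Full synthetic-cohort specification."""

    archetypes: tuple  # of ArchetypeConfig
    nuclei_per_sample: int = 100
    theta_cng: float = 0.10
    seed: int = 0


@dataclass(frozen=True)
class SyntheticCase:
    """One generated case: inputs plus generation ground truth."""

    case_id: str
    archetype: str
    nuclei: tuple
    case_fields: Mapping[str, object]
    truth: Mapping[str, object]


@dataclass(frozen=True)
class CohortBundle:
    cases: tuple  # of SyntheticCase
    config: CohortConfig

    def nucleus_rows(self) -> list:
        """Rows for the nucleus-table format."""
        rows = []
        for case in self.cases:
            for nuc in case.nuclei:
                tok = ";".join("+".join(sorted(t.channels)) for t in nuc.tokens)
                rows.append((case.case_id, nuc.nucleus_id, tok, "NA"))
        return rows


def _combination_weights_from_reference(cohort: str) -> dict:
    total = 0
    weights: dict = {}
    for grp, classes, composite, count in reference_pattern_counts():
        if grp == cohort:
            weights[(classes, composite)] = weights.get((classes, composite), 0) + count
            total += count
    return {k: v / total for k, v in weights.items()}


def default_config(
    seed: int = 0,
    n_pos_conc: int = 189,
    n_pos_disc: int = 33,
    n_neg_disc: int = 17,
    n_neg_conc: int = 2444,
    sectioning_rate: float = 0.15,
    nuclei_per_sample: int = 100,
) -> CohortConfig:
    """Reference-calibrated cohort configuration.

    Archetype case counts default to the reference cohort's final
    concordance-class sizes; pattern-combination weights are the
    reference combination frequencies; copy-number-gain weights are the
    per-group reference category fractions; the rearranged-fraction Beta
    is moment-matched to the positive samples of the reference
    sequencing table (mean ~0.45, sd ~0.17).
    """
    cng = _reference_cng_weights()
    pos_common = dict(rearranged_mean=0.45, rearranged_conc=8.0)
    neg_common = dict(rearranged_mean=0.04, rearranged_conc=30.0)
    archetypes = (
        ArchetypeConfig(
            name="positive_concordant",
            n_cases=n_pos_conc,
            fish_positive=True,
            sectioning_rate=sectioning_rate,
            combination_weights=_combination_weights_from_reference("concordant"),
            cng_weights=cng["positive_concordant"],
            ihc_weights={
                IhcStaining.STRONG_3PLUS: 0.68,
                IhcStaining.STRONG_2PLUS: 0.30,
                IhcStaining.DOT_LIKE: 0.02,
            },
            ngs_rate=4 / 189,
            ngs_partner_weights={"EML4": 0.9, "HIP1": 0.1},
            female_rate=0.55,
            **pos_common,
        ),
        ArchetypeConfig(
            name="positive_discordant",
            n_cases=n_pos_disc,
            fish_positive=True,
            sectioning_rate=sectioning_rate,
            combination_weights=_combination_weights_from_reference("discordant"),
            cng_weights=cng["positive_discordant"],
            ihc_weights={
                IhcStaining.NONE: 0.60,
                IhcStaining.WEAK_1PLUS: 0.25,
                IhcStaining.STIPPLED: 0.15,
            },
            ngs_rate=11 / 33,
            ngs_partner_weights={"EML4": 1.0},
            female_rate=0.39,
            **pos_common,
        ),
        ArchetypeConfig(
            name="negative_discordant",
            n_cases=n_neg_disc,
            fish_positive=False,
            sectioning_rate=sectioning_rate,
            cng_weights=cng["negative_discordant"],
            ihc_weights={
                IhcStaining.STRONG_3PLUS: 0.5,
                IhcStaining.STRONG_2PLUS: 0.5,
            },
            ngs_rate=2 / 17,
            ngs_partner_weights={"EML4": 0.5, "CSFT3": 0.5},
            female_rate=0.82,
            **neg_common,
        ),
        ArchetypeConfig(
            name="negative_concordant",
            n_cases=n_neg_conc,
            fish_positive=False,
            sectioning_rate=sectioning_rate,
            cng_weights={"<=3": 0.90, "4-6": 0.07, "7-9": 0.02, "10+": 0.01},
            ihc_weights={
                IhcStaining.NONE: 0.85,
                IhcStaining.WEAK_1PLUS: 0.10,
                IhcStaining.STIPPLED: 0.05,
            },
            ngs_rate=58 / 2444,
            female_rate=0.34,
            **neg_common,
        ),
    )
    return CohortConfig(
        archetypes=archetypes, nuclei_per_sample=nuclei_per_sample, seed=seed
    )


def _reference_cng_weights() -> dict:
    path = resources.files("alkfish.data") / "cng_categories.tsv"
    groups = ("positive_discordant", "negative_discordant", "positive_concordant")
    counts: dict = {g: {} for g in groups}
    with path.open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for rec in reader:
            for g in groups:
                counts[g][rec["category"]] = int(rec[g])
    out = {}
    for g in groups:
        total = sum(counts[g].values())
        out[g] = {cat: counts[g][cat] / total for cat in CNG_CATEGORIES}
    return out


_CNG_COPY_RANGES = {"4-6": (4, 6), "7-9": (7, 9), "10+": (10, 14)}


def _draw_weighted(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights.keys())
    probs = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _draw_beta(rng: np.random.Generator, mean: float, conc: float) -> float:
    return float(rng.beta(mean * conc, (1.0 - mean) * conc))


def generate_case(
    config: CohortConfig, archetype: ArchetypeConfig, rng: np.random.Generator,
    case_id: str = "case",
) -> SyntheticCase:
    """Generate one case: nucleus observations, case metadata fields and
    the generation ground truth."""
    n = config.nuclei_per_sample

    # --- true FISH state
    if archetype.fish_positive:
        classes, composite = _draw_weighted(rng, archetype.combination_weights)
        if composite:
            frac = float(rng.uniform(0.16, 0.26))
        else:
            frac = _draw_beta(rng, archetype.rearranged_mean, archetype.rearranged_conc)
            frac = min(max(frac, 0.22), 0.95)
        if composite and len(classes) == 1:
            # subthreshold single-pattern positives are dominated by the
            # canonical variant plus its sectioning derivative
            variant_pool = [
                CANONICAL_VARIANTS[classes[0]],
                _sectioned(CANONICAL_VARIANTS[classes[0]]),
            ]
            weights = np.array([0.70, 0.30])
            if variant_pool[1] is None:
                variant_pool, weights = variant_pool[:1], np.array([1.0])
        else:
            variant_pool = [CANONICAL_VARIANTS[c] for c in classes]
            weights = np.array(archetype.mixture_weights[: len(classes)], dtype=float)
        weights = weights / weights.sum()
    else:
        classes, composite = (), False
        frac = min(_draw_beta(rng, archetype.rearranged_mean,
                              archetype.rearranged_conc), 0.12)
        variant_pool = [CANONICAL_VARIANTS[PatternClass.INVERSION]]
        weights = np.array([1.0])

    # --- CNG profile
    cng_category = _draw_weighted(rng, archetype.cng_weights)
    if cng_category == "<=3":
        elevated_frac = 0.0
    else:
        elevated_frac = float(rng.uniform(max(config.theta_cng + 0.02, 0.12), 0.30))

    # --- render nuclei
    nuclei = []
    for i in range(n):
        rearranged = rng.random() < frac
        elevated = rng.random() < elevated_frac
        if elevated:
            lo, hi = _CNG_COPY_RANGES[cng_category]
            copies = int(rng.integers(lo, hi + 1))
        else:
            copies = int(rng.integers(2, 4)) if not rearranged else 1
        tokens: tuple = (_INTACT,) * copies
        if rearranged:
            res = variant_pool[int(rng.choice(len(weights), p=weights))]
            tokens = tokens + tuple(res)
        if archetype.sectioning_rate and rng.random() < archetype.sectioning_rate:
            if len(tokens) > 1:
                drop = int(rng.integers(len(tokens)))
                tokens = tokens[:drop] + tokens[drop + 1:]
        nuclei.append(
            NucleusObservation(tokens=tokens, nucleus_id=f"{case_id}:{i}")
        )

    # --- case metadata
    staining = _draw_weighted(rng, archetype.ihc_weights)
    ihc_repeat = ""
    if staining is IhcStaining.DOT_LIKE:
        # dot-like positivity only emerges at the reevaluation stage
        staining, ihc_repeat = IhcStaining.NONE, IhcStaining.DOT_LIKE.value
    sex = "F" if rng.random() < archetype.female_rate else "M"
    age = int(np.clip(rng.normal(65, 10), 23, 91))
    sequenced = rng.random() < archetype.ngs_rate
    fields: dict = {
        "case_id": case_id,
        "age": age,
        "sex": sex,
        "histology": "adenocarcinoma_nos",
        "ihc_staining": staining.value,
        "ihc_repeat": ihc_repeat,
    }
    if sequenced:
        fields.update(
            dna_ng=round(float(rng.uniform(80, 300)), 1),
            rna_conc=round(float(rng.uniform(11, 60)), 1),
            dv200=round(float(rng.uniform(35, 90)), 1),
            library_conc=round(float(rng.uniform(3.5, 12)), 2),
            tumor_content=round(float(rng.uniform(0.25, 0.9)), 2),
        )
        if archetype.ngs_partner_weights and rng.random() < (
            0.9 if archetype.name in ("positive_concordant", "negative_discordant")
            else 0.1
        ):
            partner = _draw_weighted(rng, archetype.ngs_partner_weights)
            fields["fusion_evidence"] = f"{partner}:{5 + int(rng.poisson(10))}"

    truth = {
        "case_id": case_id,
        "archetype": archetype.name,
        "fish_positive": archetype.fish_positive,
        "pattern_classes": "+".join(c.value for c in classes),
        "composite": composite,
        "rearranged_fraction": frac,
        "cng_category": cng_category,
        "elevated_fraction": elevated_frac,
    }
    return SyntheticCase(
        case_id=case_id,
        archetype=archetype.name,
        nuclei=tuple(nuclei),
        case_fields=fields,
        truth=truth,
    )


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full cohort, reproducibly from ``config.seed``.

    Each case uses an independent counter-derived random stream, so the
    output for a given (archetype, case index) does not depend on how
    many cases other archetypes request.
    """
    cases = []
    for ai, archetype in enumerate(config.archetypes):
        for ci in range(archetype.n_cases):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(ai, ci))
            )
            case_id = f"{archetype.name}-{ci:04d}"
            cases.append(generate_case(config, archetype, rng, case_id=case_id))
    return CohortBundle(cases=tuple(cases), config=config)
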