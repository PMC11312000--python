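# Methods

This note documents the scoring model, the statistical procedures, the
synthetic-data generator and the numerical/design choices behind
`alkfish`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and per-nucleus classification

A nucleus observation is a multiset of signal tokens; a token is the
non-empty set of fluorescence channels found co-localized at one spot
(`O` = 3′ ALK arm, orange; `G` = 5′ ALK arm, green; `B` = EML4 arm,
blue). Any token containing both `O` and `G` is an intact fusion — an
unrearranged ALK locus — and the intact-fusion count of a nucleus is
its ALK copy number. Classification removes all intact fusions and
matches the residual multiset against the signature table (see README)
by **exact multiset equality**: multiplicities matter, so `OB` and
`OB/OB` are distinct residues. The variant lists enumerate complete
signal configurations, which makes exact matching the faithful reading;
it also guarantees unambiguity (no residue maps to two classes — the
table is checked for this at import).

Consequences of exact matching worth knowing:

* An empty residue is `NOT_REARRANGED`.
* A non-empty residue absent from the table (for example two
  independent splits in one polysomic nucleus, `OB/GB/OB/GB`) is
  `UNCLASSIFIED`: surfaced, flagged as atypical at sample level, never
  counted toward positivity. The guideline sources do not state how
  such nuclei were handled; surfacing rather than guessing is the
  conservative choice.
* 3′-deletion residues (`GB`, `GB/B`, `GB/GB/B` — orange arm lost,
  green retained) are in the table but hard-wired to never count toward
  positivity: under the valid scoring guidelines an isolated 5′ signal
  does not demonstrate an ALK split. They are recorded and raise the
  sample's atypical flag, because such samples can still be
  fusion-positive on sequencing.

The dual-colour break-apart classifier sees only the two ALK channels.
A nucleus is positive on an isolated orange plus isolated green pair at
least two signal diameters apart, or on an isolated orange with no
green; a pair closer than two diameters is a *short break* — scored
negative, flagged for tri-colour retesting. The two-diameter distance
is measured upstream at image analysis and enters this package only as
the `split_ok` flag; the package never re-scores distances. For
cross-probe consistency checks a tri-colour observation is re-encoded
by erasing the blue channel from every token (dropping tokens that
become empty): every translocation, inversion or 5′-deletion signature
then reads positive or short-break under the break-apart rules, never
negative — this is a property test in the suite.

## Sample-level scoring

* **Enumeration**: nuclei with at least one signal are enumerable; a
  sample needs ≥ 50 (100 are read when material allows). Below 50 the
  sample is `INSUFFICIENT` and excluded from every cohort denominator.
* **Positivity**: countable rearranged nuclei ≥ 15% of enumerated
  nuclei, cut-off inclusive. The 15% threshold is a fraction of
  *enumerated* nuclei; the 4% minority-retention threshold below is a
  fraction of *rearranged* nuclei. A positive call is *composite* when
  no single variant reaches 15% on its own.
* **Pattern-set derivation**: the predominant variant is the one with
  the highest share of rearranged nuclei (tie → more signals, then
  lexicographically smallest label; ties are logged — none occur in the
  reference data). Every other variant survives only if it holds ≥ 4%
  of rearranged nuclei and is **not derivable** from the predominant
  residue. Derivable means sub-multiset under whole-token equality:
  sectioning a nucleus during tissue processing removes whole signals
  but cannot strip one channel out of a co-localized spot. Derivable
  variants fold into the predominant's class; surviving variants are
  grouped by class, ordered by summed share (descending), and truncated
  at three classes (truncation is logged, never silent; more than three
  classes were never observed in the reference data, so the cap matches
  the observed vocabulary). This rule is validated two ways: every
  two-class combination in the reference vocabulary consists of a
  non-derivable minority, and for every ordered pair of canonical
  variants the derivation keeps the minority exactly when it is not a
  sub-multiset of the predominant (for example `O` folds into `O/GB`,
  so "translocation + 5′ deletion" can never be emitted — and indeed
  never occurs in the reference counts).
* **Copy-number gain**: per-nucleus copy numbers map to classes
  `<=3 / 4-6 / 7-9 / 10+`; the sample category is the highest class
  whose nucleus fraction reaches θ. The reference source assigns one
  category per sample without stating the reduction; the
  threshold-fraction rule with θ = 0.10 is this package's choice,
  exposed as `--theta-cng` / `theta` everywhere it matters.

## Assay integration

IHC: strong diffuse granular cytoplasmic staining (2+, 3+) is positive;
no staining, weak (1+) and stippled staining are negative; dot-like
staining is positive only at the reevaluation stage. A case record with
a negative primary read and a repeat observation takes the repeat's
score. Reevaluation at cohort level moves reclassified cases from
positive discordant to positive concordant, conserving the total.

NGS gates, in order, first violation reported: DNA ≥ 80 ng (inclusive
floor), RNA concentration > 10 ng/µL, DV200 > 30%, library
concentration > 3 ng/µL, tumour content > 20% (strict, per each
criterion's wording). Fusions need ≥ 5 unique supporting reads. CNV
amplification calling is not modelled beyond carrying the evidence:
per-gene thresholds are panel-specific and only one anchor value is
documented for one purity, so no purity-scaling formula is invented.

Sensitivity of FISH is `pos_conc / (pos_conc + neg_disc)`, specificity
`neg_conc / (neg_conc + pos_disc)` — the standard forms with protein
expression as reference. Reported percentages use round-half-even to
one decimal.

## Exact statistics

* **Fisher's exact test (2×K, K ≤ 4)**: full enumeration of all
  margin-consistent tables; two-sided p sums the conditional
  multivariate-hypergeometric probabilities of tables no more probable
  than the observed one (minimum-likelihood criterion, with a 1 + 1e−7
  relative guard on the comparison, matching the convention of the
  standard statistical software). Probabilities are computed in
  log-gamma space and accumulated with compensated summation; the test
  suite checks agreement to 1e−9 relative against an independent
  exact-rational enumeration oracle. Larger tables raise a capability
  error rather than falling back to approximation.
* **Cramér's V**: √(χ²/(n·min(r−1,c−1))) with Pearson χ², no continuity
  correction.
* **CI for V**: the noncentrality λ of the χ² statistic is bracketed so
  the observed statistic sits at the 2.5th/97.5th percentile of the
  noncentral χ² distribution (Brent root-finding on the CDF, λ clamped
  at 0), and each bound maps to V via √((λ+df)/(n·min(r−1,c−1))) —
  Smithson's construction, as implemented in the common R effect-size
  packages. A clamped lower λ maps to a lower bound of exactly 0.
* **Laplace smoothing**: a zero row (or, symmetrically, zero column)
  adds 1 to every cell before testing; the result is flagged.

## Synthetic cohorts

Two generators, both seeded.

**Deterministic realization** (`realize_pattern_sample`): fixed variant
counts per 100 nuclei chosen to realize a given pattern combination —
threshold samples use 30 / (20, 8) / (20, 10, 6) nuclei for 1/2/3
classes, composite samples 12 / (12, 6) / (9, 7, 5), and a composite
single-class sample carries 9 nuclei of the canonical residue's
sectioning derivative (which the folding rule re-absorbs). Each class
is rendered by its canonical residue (`OB/GB`, `O/GB`, `O`, `OB`).
These counts put every minority above the 4% retention cut-off, keep
composite variants below 15% of enumerated nuclei while their sum
clears it, and keep threshold samples' predominant variant above 15%.
The seed only shuffles nucleus order, so derived quantities are
seed-invariant. `realize_reference_pattern_cohort` applies this to the
shipped combination-count table (29 discordant + 168 concordant
samples).

**Stochastic cohorts** (`generate_cohort`): four archetypes
(positive/negative × concordant/discordant). Defaults are calibrated to
the reference cohort: combination weights are the reference combination
frequencies per group; CNG category weights are the reference per-group
fractions; the rearranged fraction of positive samples is Beta with
mean 0.45 and concentration 8 (moment-matched to the positive samples
of the reference sequencing table, which range from 16% to 90%),
truncated to [0.22, 0.95] for threshold samples and drawn uniform on
(0.16, 0.26) for composite ones; negative archetypes draw Beta(mean
0.04, conc. 30) capped at 0.12. Rearranged nuclei are rendered as
intact fusions plus the canonical residue of a variant drawn from the
combination's mixture (weights 0.65/0.25/0.10; composite single-class
samples split 0.70/0.30 between the canonical residue and its
sectioning derivative, the artifact being a minority byproduct by
construction). Each nucleus then loses one whole token with probability
`sectioning_rate` (default 0.15). Elevated-copy nuclei are drawn
independently at a per-sample fraction uniform on (θ+0.02 … 0.30) with
copy counts uniform in the drawn category's range. IHC staining, sex,
age and sequencing fields come from simple per-archetype categorical /
clipped-normal / uniform draws. One global seed expands to per-case
streams via `SeedSequence(seed, spawn_key=(archetype, case))`, so
streams are stable under case-count changes.

What the generator emulates: the variant-mixture structure, composite
positivity, sectioning artifacts that the folding rule must undo, CNG
profiles, and borderline samples that cross the 15% cut-off by counting
noise (visible in the README example). What it does not emulate:
spatial heterogeneity (multi-component tumours), inter-observer
enumeration variability, short-break geometry (the split-distance flag
is an input, and synthetic tri-colour nuclei carry `NA` there), and any
correlation between CNG and rearrangement within a nucleus beyond
independence. Passing recovery tests therefore show the scoring rules
invert this generative process — not that they are robust to every
failure mode of real slides.

Recovery behaviour worth stating: pattern-set recovery is measured over
samples the pipeline calls positive (the derivation's contract starts
there; a truly borderline sample realized below 15% is a correct
negative, not a derivation failure). The residual failure mode is a
small-sample boundary effect: in a sample with ~20 rearranged nuclei a
single sectioning-artifact nucleus already holds 5% of the rearranged
pool and, when it is not derivable from the predominant (e.g. an `OB`
remnant of a *secondary* inversion under a 5′-deletion predominant),
it appears as a spurious extra class. At the default sectioning rate
this affects a few percent of positive samples, which is why the
recovery target is 95% rather than 100%.

## Problem sizes

The test suite runs cohorts of up to 120 positive cases (100 nuclei
each) for recovery checks and 40 random tables plus ~200 fuzzed cases
for the enumeration oracle; the acceptance script renders 197 samples
of 100 nuclei. These sizes give binomial noise well below every margin
tested while keeping the whole suite in a few seconds.

## Known limitations

* The specificity wording in the reference description is internally
  inconsistent; the standard form implemented here reproduces the
  reported value only to one decimal (98.67 vs 98.6).
* The CNG sample-category reduction (θ-fraction rule) is a documented
  package choice, not a sourced rule.
* Exact enumeration is limited to 2×K, K ≤ 4; no Monte Carlo fallback.
* Nuclei with more than one rearranged configuration are surfaced as
  `UNCLASSIFIED` rather than decomposed.
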