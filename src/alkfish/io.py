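"""Readers, writers, fixtures and the end-to-end pipeline report.

File formats are UTF-8 tab-separated text with ``#`` comment lines and
required headers — chosen so fixtures diff cleanly.

Nucleus table: one row per nucleus with columns ``sample_id``,
``nucleus_id``, ``tokens`` (semicolon-separated signal tokens, ``+``
joining co-localized channels, e.g. ``O+G;O+B;G+B``) and ``split_ok``
(``0``/``1``/``NA`` — the break-apart two-diameter distance flag,
measured upstream).

Case table: one row per case with IHC staining (and optional repeat),
demographics and optional sequencing fields.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .assay_integration import (
    CaseRecord,
    Concordance,
    ConcordanceCounts,
    FusionEvidence,
    IhcObservation,
    IhcStaining,
    NgsSample,
    CohortSummary,
    cohort_summaries,
)
from .fish_signals import NucleusObservation, SignalToken, token
from .sample_calling import (
    CNG_CATEGORIES,
    FishSampleResult,
    FishStatus,
    summarize_sample,
)
from .stats import AssociationResult, ContingencyTable, associate, build_pattern_table

__all__ = [
    "NUCLEUS_COLUMNS",
    "NucleusTableError",
    "RowError",
    "read_nucleus_table",
    "write_nucleus_table",
    "read_case_table",
    "write_case_table",
    "write_sample_results",
    "sample_result_row",
    "reference_concordance_counts",
    "reference_pattern_contingency",
    "PipelineReport",
    "run_pipeline",
]

NUCLEUS_COLUMNS = ("sample_id", "nucleus_id", "tokens", "split_ok")
CASE_COLUMNS = (
    "case_id", "age", "sex", "histology", "ihc_staining", "ihc_repeat",
    "dna_ng", "rna_conc", "dv200", "library_conc", "tumor_content",
    "fusion_evidence",
)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


class NucleusTableError(ValueError):
    """Malformed nucleus table; carries per-row errors with line numbers."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = tuple(errors)
        detail = "; ".join(f"line {e.line}: {e.message}" for e in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} malformed row(s): {detail}{more}")


def _parse_tokens(text: str) -> tuple:
    text = text.strip()
    if not text:
        return ()
    return tuple(sorted(token(part) for part in text.split(";")))


def _parse_split(text: str) -> Optional[bool]:
    text = text.strip().upper()
    if text in ("", "NA", "NONE"):
        return None
    if text in ("0", "FALSE"):
        return False
    if text in ("1", "TRUE"):
        return True
    raise ValueError(f"invalid split_ok value {text!r}")


def read_nucleus_table(path, strict: bool = True) -> tuple:
    """Parse a nucleus table.

    Returns ``(samples, errors)`` where ``samples`` maps sample_id to its
    list of :class:`NucleusObservation` (file order preserved) and
    ``errors`` collects malformed rows with line numbers.  With
    ``strict`` (default) any malformed row raises
    :class:`NucleusTableError` instead.
    """
    samples: dict = {}
    errors: list = []
    with open(path, encoding="utf-8") as fh:
        header: Optional[list] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in NUCLEUS_COLUMNS if c not in header]
                if missing:
                    raise NucleusTableError(
                        [RowError(lineno, f"missing column(s) {missing}")]
                    )
                continue
            rec = dict(zip(header, fields))
            try:
                obs = NucleusObservation(
                    tokens=_parse_tokens(rec.get("tokens", "")),
                    split_distance_ok=_parse_split(rec.get("split_ok", "NA")),
                    nucleus_id=rec.get("nucleus_id", ""),
                )
            except ValueError as exc:
                errors.append(RowError(lineno, str(exc)))
                continue
            sid = rec.get("sample_id", "").strip()
            if not sid:
                errors.append(RowError(lineno, "empty sample_id"))
                continue
            samples.setdefault(sid, []).append(obs)
        if header is None:
            raise NucleusTableError([RowError(0, "empty file (no header)")])
    if errors and strict:
        raise NucleusTableError(errors)
    return samples, errors


def write_nucleus_table(samples: Mapping, path) -> None:
    """Inverse of :func:`read_nucleus_table` (lossless round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(NUCLEUS_COLUMNS) + "\n")
        for sid in samples:
            for obs in samples[sid]:
                tok = ";".join(
                    "+".join(sorted(t.channels)) for t in obs.tokens
                )
                split = (
                    "NA"
                    if obs.split_distance_ok is None
                    else str(int(obs.split_distance_ok))
                )
                fh.write(f"{sid}\t{obs.nucleus_id}\t{tok}\t{split}\n")


def _parse_fusion_evidence(text: str) -> tuple:
    text = text.strip()
    if not text or text.lower() == "none":
        return ()
    out = []
    for part in text.split(","):
        partner, _, reads = part.partition(":")
        out.append(FusionEvidence(partner.strip(), int(reads)))
    return tuple(out)


def _opt_float(rec: Mapping, key: str) -> Optional[float]:
    v = str(rec.get(key, "")).strip()
    return float(v) if v not in ("", "NA") else None


def read_case_table(path) -> list:
    """Parse a case-metadata table into :class:`CaseRecord` objects
    (without FISH results; those attach in :func:`run_pipeline`)."""
    records = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for rec in reader:
            ihc = IhcObservation(IhcStaining(rec["ihc_staining"].strip()))
            repeat_txt = rec.get("ihc_repeat", "").strip()
            repeat = (
                IhcObservation(IhcStaining(repeat_txt), is_reevaluation=True)
                if repeat_txt
                else None
            )
            ngs = None
            if any(str(rec.get(k, "")).strip() not in ("", "NA")
                   for k in ("dna_ng", "fusion_evidence")):
                ngs = NgsSample(
                    dna_ng=_opt_float(rec, "dna_ng"),
                    rna_conc=_opt_float(rec, "rna_conc"),
                    dv200=_opt_float(rec, "dv200"),
                    library_conc=_opt_float(rec, "library_conc"),
                    tumor_content=_opt_float(rec, "tumor_content"),
                    fusion_evidence=_parse_fusion_evidence(
                        rec.get("fusion_evidence", "")
                    ),
                )
            age_txt = str(rec.get("age", "")).strip()
            records.append(
                CaseRecord(
                    case_id=rec["case_id"].strip(),
                    age=int(age_txt) if age_txt else None,
                    sex=rec.get("sex", "").strip() or None,
                    histology=rec.get("histology", "").strip() or None,
                    ihc=ihc,
                    ihc_repeat=repeat,
                    ngs=ngs,
                )
            )
    return records


def write_case_table(rows: Iterable[Mapping], path) -> None:
    """Write case-metadata rows (mappings of column -> value)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CASE_COLUMNS) + "\n")
        for rec in rows:
            fh.write(
                "\t".join(str(rec.get(c, "")) for c in CASE_COLUMNS) + "\n"
            )


def sample_result_row(result: FishSampleResult) -> dict:
    """Flatten a sample result for the delimited writer."""
    return {
        "sample_id": result.sample_id,
        "status": str(result.status),
        "n_enumerated": result.n_enumerated,
        "percent_rearranged": f"{result.percent_rearranged:.1f}",
        "pattern_set": "+".join(str(c) for c, _ in result.pattern_set),
        "cng_category": result.cng_category,
        "atypical_flag": int(result.atypical_flag),
        "composite_positive": int(result.composite_positive),
    }


def write_sample_results(results: Iterable[FishSampleResult], path) -> None:
    cols = (
        "sample_id", "status", "n_enumerated", "percent_rearranged",
        "pattern_set", "cng_category", "atypical_flag", "composite_positive",
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for res in results:
            row = sample_result_row(res)
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def reference_concordance_counts() -> dict:
    """The shipped reference cohort concordance counts, as a dict."""
    path = resources.files("alkfish.data") / "concordance_counts.tsv"
    out = {}
    with path.open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for rec in reader:
            out[rec["key"]] = int(rec["value"])
    return out


def reference_pattern_contingency() -> ContingencyTable:
    """Concordance-group x pattern-set-size table from the shipped
    reference combination counts."""
    from .synthetic_cohort import reference_pattern_counts

    return build_pattern_table(
        (grp, len(classes))
        for grp, classes, _composite, count in reference_pattern_counts()
        for _ in range(count)
    )


@dataclass(frozen=True)
class PipelineReport:
    """Deterministic end-to-end report of one cohort analysis."""

    schema_version: int
    summary: CohortSummary
    pattern_table: Optional[ContingencyTable]
    association: Optional[AssociationResult]
    cng_table: Mapping[str, Mapping[str, int]]
    cases: tuple  # of per-case dicts
    exclusions: tuple  # of (case_id, reason)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "summary": {
                "counts": asdict(self.summary.counts),
                "discordant_pct": self.summary.discordant_pct,
                "pos_disc_pct": self.summary.pos_disc_pct,
                "neg_disc_pct": self.summary.neg_disc_pct,
                "pos_disc_of_fish_positive_pct":
                    self.summary.pos_disc_of_fish_positive_pct,
                "neg_disc_of_fish_negative_pct":
                    self.summary.neg_disc_of_fish_negative_pct,
                "sensitivity_pct": self.summary.sensitivity_pct,
                "specificity_pct": self.summary.specificity_pct,
            },
            "pattern_table": (
                None
                if self.pattern_table is None
                else {
                    "rows": list(self.pattern_table.row_labels),
                    "cols": list(self.pattern_table.col_labels),
                    "counts": [list(r) for r in self.pattern_table.counts],
                }
            ),
            "association": (
                None if self.association is None else asdict(self.association)
            ),
            "cng_table": {g: dict(v) for g, v in self.cng_table.items()},
            "cases": list(self.cases),
            "exclusions": [list(e) for e in self.exclusions],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def format_text(self) -> str:
        s = self.summary
        lines = [
            "cohort summary",
            f"  analyzed cases: {s.counts.total}",
            f"  positive concordant: {s.counts.pos_conc}",
            f"  positive discordant: {s.counts.pos_disc}",
            f"  negative discordant: {s.counts.neg_disc}",
            f"  negative concordant: {s.counts.neg_conc}",
            f"  discordant overall: {s.discordant_pct}%"
            f" (positive {s.pos_disc_pct}%, negative {s.neg_disc_pct}%)",
            f"  positive discordant among FISH-positive:"
            f" {s.pos_disc_of_fish_positive_pct}%",
            f"  FISH sensitivity: {s.sensitivity_pct}%"
            f"  specificity: {s.specificity_pct}%",
        ]
        if self.association is not None:
            a = self.association
            lines += [
                "pattern-count association (concordance x pattern-set size)",
                f"  Fisher exact p = {a.p_value:.3g}; chi2 = {a.chi_square:.2f}"
                f" (df {a.df}); Cramer's V = {a.cramers_v:.2f}"
                f" (95% CI {a.v_ci[0]:.2f}, {a.v_ci[1]:.2f})",
            ]
        if self.exclusions:
            lines.append(f"  excluded cases: {len(self.exclusions)}")
        return "\n".join(lines)


def run_pipeline(
    samples: Mapping,
    cases: Sequence[CaseRecord],
    theta_cng: float = 0.10,
) -> PipelineReport:
    """Tie all stages together for one cohort.

    ``samples`` maps case_id to its nucleus observations; ``cases``
    carries the per-case metadata.  Samples with fewer than 50
    enumerable nuclei are excluded from every denominator and listed
    under exclusions.  Output is deterministic for identical inputs.
    """
    from dataclasses import replace as dc_replace

    results: dict = {}
    exclusions: list = []
    for sid in sorted(samples):
        res = summarize_sample(samples[sid], sample_id=sid, theta_cng=theta_cng)
        results[sid] = res
        if res.status is FishStatus.INSUFFICIENT:
            exclusions.append((sid, "fewer than 50 enumerable nuclei"))

    counts = {c: 0 for c in Concordance}
    case_rows = []
    cng_table: dict = {}
    pattern_samples = []
    for case in sorted(cases, key=lambda c: c.case_id):
        fish = results.get(case.case_id)
        if fish is None:
            exclusions.append((case.case_id, "no nucleus table"))
            continue
        case = dc_replace(case, fish=fish)
        conc = case.concordance
        counts[conc] += 1
        row = {
            "case_id": case.case_id,
            "concordance": str(conc),
            "ihc_status": str(case.ihc_status),
            **sample_result_row(fish),
        }
        case_rows.append(row)
        if conc is not Concordance.EXCLUDED:
            cng_table.setdefault(str(conc), {c: 0 for c in CNG_CATEGORIES})
            cng_table[str(conc)][fish.cng_category] += 1
            if conc in (Concordance.POS_CONC, Concordance.POS_DISC):
                group = (
                    "concordant" if conc is Concordance.POS_CONC else "discordant"
                )
                pattern_samples.append((group, len(fish.pattern_set)))

    cc = ConcordanceCounts(
        pos_conc=counts[Concordance.POS_CONC],
        pos_disc=counts[Concordance.POS_DISC],
        neg_disc=counts[Concordance.NEG_DISC],
        neg_conc=counts[Concordance.NEG_CONC],
    )
    summary = cohort_summaries(cc)

    pattern_table = None
    association = None
    if pattern_samples:
        pattern_table = build_pattern_table(pattern_samples)
        if pattern_table.n >= 2:
            association = associate(pattern_table)

    return PipelineReport(
        schema_version=SCHEMA_VERSION,
        summary=summary,
        pattern_table=pattern_table,
        association=association,
        cng_table=cng_table,
        cases=tuple(case_rows),
        exclusions=tuple(sorted(exclusions)),
    )
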