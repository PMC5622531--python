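"""Per-patient, per-disease detection from the three EHR sources.

A patient is called a case for a panel disease if at least one source fires:
a matching ICD-10 billing code, a matching drug prescription (ATC), or a
term mention in free text.  Autoimmune comorbidities are chronic, so a
single detection at any time point suffices — calls are invariant to event
dates.

Text candidates can be adjudicated by human reviewers; under the default
``consensus`` policy a text case requires both reviewers to approve, and
disagreements stay unresolved (reported separately, excluded from case
counts).  Negation or context handling is deliberately absent: raw-match
mode without votes is over-sensitive by construction and labeled as such.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._text import fold_text, levenshtein_leq1
from .cohort import EhrBundle
from .errors import AdjudicationError
from .terminology import DiseaseMapping, icd_matches, atc_matches

__all__ = [
    "TextMatch",
    "AdjudicationItem",
    "PhenotypeCall",
    "SourceAttribution",
    "detect_icd_cases",
    "detect_drug_cases",
    "scan_documents",
    "adjudicate",
    "combine_sources",
    "attribute_sources",
    "calls_to_frame",
    "attributions_to_frame",
]

_WORD_RE = re.compile(r"\w+")


@dataclass(frozen=True)
class TextMatch:
    """One term hit in one document.

    Spans are 0-based half-open offsets over Unicode code points of the
    accent-folded text; ``orig_span`` maps back to the original document.
    """

    doc_id: str
    patient_id: str
    dui: str
    pattern_label: str
    span: tuple[int, int]
    snippet: str
    orig_span: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class AdjudicationItem:
    patient_id: str
    dui: str
    votes: tuple[tuple[str, str], ...]  # (reviewer_id, "approve"|"reject")
    resolution: str  # "case" | "non_case" | "unresolved"


@dataclass(frozen=True)
class PhenotypeCall:
    patient_id: str
    dui: str
    present: bool
    sources: frozenset[str]  # subset of {"text", "icd", "drug"}

    def __post_init__(self) -> None:
        if self.present != bool(self.sources):
            raise ValueError("present flag must equal (sources non-empty)")


@dataclass(frozen=True)
class SourceAttribution:
    """Per-disease partition of cases by detecting source class."""

    dui: str
    n_text_only: int
    n_structured_only: int
    n_both: int

    @property
    def n_total(self) -> int:
        return self.n_text_only + self.n_structured_only + self.n_both

    def proportions(self) -> tuple[float | None, float | None, float | None]:
        if self.n_total == 0:
            return (None, None, None)
        t = self.n_total
        return (self.n_text_only / t, self.n_structured_only / t, self.n_both / t)


def detect_icd_cases(
    bundle: EhrBundle,
    mappings: Mapping[str, DiseaseMapping],
    cohort: set[str],
) -> set[tuple[str, str]]:
    """(patient, disease) pairs with at least one matching billing code."""
    out: set[tuple[str, str]] = set()
    diag = bundle.diagnoses[bundle.diagnoses["patient_id"].isin(cohort)]
    if not len(diag):
        return out
    # dedupe on (patient, code): chronic-disease rule ignores dates/repeats
    pairs = diag[["patient_id", "code"]].drop_duplicates()
    unique_codes = pairs["code"].unique()
    for m in mappings.values():
        hit = {c for c in unique_codes if any(icd_matches(p, c) for p in m.icd)}
        if hit:
            for pid in pairs.loc[pairs["code"].isin(hit), "patient_id"]:
                out.add((pid, m.dui))
    return out


def detect_drug_cases(
    bundle: EhrBundle,
    mappings: Mapping[str, DiseaseMapping],
    cohort: set[str],
) -> set[tuple[str, str]]:
    """(patient, disease) pairs with at least one matching prescription."""
    out: set[tuple[str, str]] = set()
    rx = bundle.prescriptions[bundle.prescriptions["patient_id"].isin(cohort)]
    if not len(rx):
        return out
    pairs = rx[["patient_id", "code"]].drop_duplicates()
    unique_codes = pairs["code"].unique()
    for m in mappings.values():
        if not m.atc:
            continue
        hit = {c for c in unique_codes if any(atc_matches(p, c) for p in m.atc)}
        if hit:
            for pid in pairs.loc[pairs["code"].isin(hit), "patient_id"]:
                out.add((pid, m.dui))
    return out


def scan_documents(
    bundle: EhrBundle,
    mappings: Mapping[str, DiseaseMapping],
    cohort: set[str],
) -> list[TextMatch]:
    """All non-overlapping term matches over the cohort's documents.

    Matching is case-insensitive over accent-folded text.  Fuzzy patterns
    additionally match whole word tokens within edit distance 1 of the
    pattern's literal form.
    """
    compiled = [
        (m.dui, t.label, t.compiled(), t.literal() if t.fuzzy else None)
        for m in mappings.values()
        for t in m.terms
    ]
    matches: list[TextMatch] = []
    docs = bundle.documents[bundle.documents["patient_id"].isin(cohort)]
    for row in docs.itertuples(index=False):
        text = str(row.text)
        if not text:
            continue
        folded, offsets = fold_text(text)
        for dui, label, rx, fuzzy_lit in compiled:
            seen_spans: set[tuple[int, int]] = set()
            for mo in rx.finditer(folded):
                span = (mo.start(), mo.end())
                seen_spans.add(span)
                matches.append(
                    TextMatch(
                        doc_id=str(row.doc_id),
                        patient_id=row.patient_id,
                        dui=dui,
                        pattern_label=label,
                        span=span,
                        snippet=folded[span[0] : span[1]],
                        orig_span=_orig_span(span, offsets, len(text)),
                    )
                )
            if fuzzy_lit and " " not in fuzzy_lit:
                for wo in _WORD_RE.finditer(folded):
                    span = (wo.start(), wo.end())
                    if span in seen_spans:
                        continue
                    token = wo.group(0).lower()
                    if levenshtein_leq1(token, fuzzy_lit):
                        matches.append(
                            TextMatch(
                                doc_id=str(row.doc_id),
                                patient_id=row.patient_id,
                                dui=dui,
                                pattern_label=f"{label}~1",
                                span=span,
                                snippet=folded[span[0] : span[1]],
                                orig_span=_orig_span(span, offsets, len(text)),
                            )
                        )
    return matches


def _orig_span(span: tuple[int, int], offsets: list[int], orig_len: int) -> tuple[int, int]:
    start, end = span
    o_start = offsets[start] if start < len(offsets) else orig_len
    o_end = offsets[end - 1] + 1 if end - 1 < len(offsets) else orig_len
    return (o_start, o_end)


def adjudicate(
    matches: Sequence[TextMatch],
    votes: pd.DataFrame,
    policy: str = "consensus",
) -> list[AdjudicationItem]:
    """Resolve reviewer votes per (patient, disease) item.

    *votes* columns: ``patient_id, dui, reviewer_id, vote`` with vote in
    {approve, reject}.  Policies: ``consensus`` (case iff every reviewer
    approves, mixed votes unresolved), ``any_approve`` (case iff at least
    one approves), ``single_reader`` (first reviewer's vote decides).
    A vote on a pair with no text match is an error.
    """
    if policy not in {"consensus", "any_approve", "single_reader"}:
        raise ValueError(f"unknown adjudication policy {policy!r}")
    match_pairs = {(m.patient_id, m.dui) for m in matches}
    items: list[AdjudicationItem] = []
    for (pid, dui), grp in votes.groupby(["patient_id", "dui"], sort=True):
        if (pid, dui) not in match_pairs:
            raise AdjudicationError(
                f"vote on ({pid}, {dui}) which has no highlighted term occurrence"
            )
        vs = tuple(sorted(zip(grp["reviewer_id"].astype(str), grp["vote"].astype(str))))
        bad = [v for _, v in vs if v not in {"approve", "reject"}]
        if bad:
            raise AdjudicationError(f"invalid vote value(s) {bad} on ({pid}, {dui})")
        approvals = [v == "approve" for _, v in vs]
        if policy == "consensus":
            if all(approvals):
                res = "case"
            elif not any(approvals):
                res = "non_case"
            else:
                res = "unresolved"
        elif policy == "any_approve":
            res = "case" if any(approvals) else "non_case"
        else:  # single_reader
            res = "case" if approvals[0] else "non_case"
        items.append(AdjudicationItem(patient_id=pid, dui=dui, votes=vs, resolution=res))
    return items


def text_cases_from_matches(matches: Sequence[TextMatch]) -> set[tuple[str, str]]:
    """Raw-match text cases (over-sensitive: no human validation)."""
    return {(m.patient_id, m.dui) for m in matches}


def text_cases_from_adjudication(items: Sequence[AdjudicationItem]) -> set[tuple[str, str]]:
    """Adjudicated text cases: resolution == 'case' only."""
    return {(i.patient_id, i.dui) for i in items if i.resolution == "case"}


def combine_sources(
    icd_cases: set[tuple[str, str]],
    drug_cases: set[tuple[str, str]],
    text_cases: set[tuple[str, str]],
    cohort: set[str],
    panel_duis: Iterable[str],
) -> list[PhenotypeCall]:
    """One call per (patient, disease): present iff any source fired (OR)."""
    calls: list[PhenotypeCall] = []
    for pid in sorted(cohort):
        for dui in panel_duis:
            key = (pid, dui)
            sources = set()
            if key in text_cases:
                sources.add("text")
            if key in icd_cases:
                sources.add("icd")
            if key in drug_cases:
                sources.add("drug")
            calls.append(
                PhenotypeCall(
                    patient_id=pid, dui=dui, present=bool(sources), sources=frozenset(sources)
                )
            )
    return calls


def attribute_sources(calls: Sequence[PhenotypeCall]) -> list[SourceAttribution]:
    """Partition each disease's cases: text-only / structured-only / both."""
    by_dui: dict[str, list[int]] = {}
    order: list[str] = []
    for c in calls:
        if c.dui not in by_dui:
            by_dui[c.dui] = [0, 0, 0]
            order.append(c.dui)
        if not c.present:
            continue
        has_text = "text" in c.sources
        has_struct = bool(c.sources & {"icd", "drug"})
        if has_text and has_struct:
            by_dui[c.dui][2] += 1
        elif has_text:
            by_dui[c.dui][0] += 1
        else:
            by_dui[c.dui][1] += 1
    return [
        SourceAttribution(dui=d, n_text_only=v[0], n_structured_only=v[1], n_both=v[2])
        for d, v in ((d, by_dui[d]) for d in order)
    ]


def calls_to_frame(calls: Sequence[PhenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in calls],
            "dui": [c.dui for c in calls],
            "present": [c.present for c in calls],
            "sources": ["+".join(sorted(c.sources)) for c in calls],
        }
    )


def attributions_to_frame(attribs: Sequence[SourceAttribution]) -> pd.DataFrame:
    rows = []
    for a in attribs:
        pt, ps, pb = a.proportions()
        rows.append(
            {
                "dui": a.dui,
                "n_total": a.n_total,
                "n_text_only": a.n_text_only,
                "n_structured_only": a.n_structured_only,
                "n_both": a.n_both,
                "prop_text_only": pt,
                "prop_structured_only": ps,
                "prop_both": pb,
            }
        )
    return pd.DataFrame(rows)
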