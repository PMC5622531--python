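"""Machine-usable disease detectors: ICD-10 patterns, ATC prefixes, text terms.

Each panel disease is expressed as a :class:`DiseaseMapping` bundling

* ICD-10 code patterns, with OR alternatives (``E271|E272``) and descendant
  semantics (a trailing ``*`` covers all descending codes, e.g. ``E10*``);
* ATC code prefixes (a stem such as ``A10A`` covers every insulin
  formulation);
* text term patterns — regular expressions applied to accent-folded,
  case-insensitive document text.

The concept-mapping step itself (MeSH to ICD-10/ATC traversal through a
terminology server) is out of scope: mappings arrive fully resolved in a
YAML/JSON config, which this module validates, compiles and applies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import yaml

from ._text import fold_text
from .errors import MappingError, PatternError

__all__ = [
    "IcdPattern",
    "AtcPattern",
    "TermPattern",
    "DiseaseMapping",
    "normalize_icd",
    "icd_matches",
    "atc_matches",
    "parse_mapping_config",
    "serialize_mapping_config",
]

ICD_STEM_RE = re.compile(r"^[A-Z]\d{2,}[0-9A-Z]*$")
# ATC levels: 1 (anatomical group), 3, 4, 5 and 7 characters (full code)
ATC_LEVEL_RE = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d{2}$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    7: re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$"),
}

# Static heuristic against catastrophic backtracking: reject a quantifier
# applied to a group whose body itself ends in a quantifier, e.g. (\w+)+
_NESTED_QUANT_RE = re.compile(r"\([^()]*[*+}][^()]*\)\s*[*+{]")


def normalize_icd(code: str) -> str:
    """Canonical billing-code form: upper-cased, dots removed."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class IcdPattern:
    """One or more ICD-10 code stems, optionally covering all descendants."""

    alternatives: tuple[str, ...]
    descendant: bool = False

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise MappingError("ICD pattern needs at least one alternative")
        for stem in self.alternatives:
            if not ICD_STEM_RE.match(stem):
                raise MappingError(f"malformed ICD-10 stem {stem!r}")

    @staticmethod
    def from_spec(spec: str) -> "IcdPattern":
        """Parse the config shorthand: ``E271|E272``, ``E10*``, ``E050|E05*``.

        A trailing ``*`` on any alternative marks the whole pattern as
        descendant-covering.
        """
        descendant = False
        alts = []
        for part in spec.split("|"):
            part = normalize_icd(part)
            if part.endswith("*"):
                descendant = True
                part = part[:-1]
            if not part:
                raise MappingError(f"empty alternative in ICD spec {spec!r}")
            alts.append(part)
        return IcdPattern(tuple(alts), descendant)

    def to_spec(self) -> str:
        star = "*" if self.descendant else ""
        return "|".join(a + star for a in self.alternatives)


def icd_matches(pattern: IcdPattern, code: str) -> bool:
    """Does a raw billing code fall under the pattern?

    The code is dot-stripped and upper-cased first.  With
    ``descendant=False`` the code must equal an alternative stem exactly;
    with ``descendant=True`` it may equal the stem or extend it.
    """
    if not code or not code.strip():
        raise MappingError("empty ICD code")
    norm = normalize_icd(code)
    if pattern.descendant:
        return any(norm.startswith(stem) for stem in pattern.alternatives)
    return any(norm == stem for stem in pattern.alternatives)


@dataclass(frozen=True)
class AtcPattern:
    """An ATC code or prefix at hierarchy level 1, 2, 3, 4 or 5."""

    prefix: str

    def __post_init__(self) -> None:
        rx = ATC_LEVEL_RE.get(len(self.prefix))
        if rx is None or not rx.match(self.prefix):
            raise MappingError(f"malformed ATC prefix {self.prefix!r}")


def atc_matches(pattern: AtcPattern, code: str) -> bool:
    """Does a full 7-character ATC code fall under the prefix?"""
    code = code.strip().upper()
    if not ATC_LEVEL_RE[7].match(code):
        raise MappingError(f"malformed ATC code {code!r} (expected 7 characters)")
    return code.startswith(pattern.prefix)


@dataclass(frozen=True)
class TermPattern:
    """A text detector: regex applied to folded text, optionally fuzzy.

    Patterns are compiled case-insensitively over accent-folded text; the
    pattern literal itself is accent-folded as well so that e.g.
    ``thyroïdite`` and ``thyroidite`` are interchangeable in configs.
    ``fuzzy=True`` additionally matches whole word tokens within edit
    distance 1 of the (literal) pattern.
    """

    pattern: str
    label: str
    fuzzy: bool = False

    def __post_init__(self) -> None:
        if _NESTED_QUANT_RE.search(self.pattern):
            raise PatternError(
                f"pattern {self.pattern!r} rejected by the backtracking guard "
                "(quantified group ending in a quantifier)"
            )
        try:
            re.compile(fold_text(self.pattern)[0], re.IGNORECASE)
        except re.error as exc:
            raise PatternError(f"pattern {self.pattern!r} does not compile: {exc}") from None

    def compiled(self) -> re.Pattern[str]:
        return re.compile(fold_text(self.pattern)[0], re.IGNORECASE)

    def literal(self) -> str:
        """Folded literal text of the pattern, for fuzzy token comparison."""
        lit = re.sub(r"\\b", "", self.pattern)
        lit = re.sub(r"\\w[+*]?", "", lit)
        lit = re.sub(r"\\s[+*]?", " ", lit)
        return fold_text(lit)[0].strip().lower()


@dataclass(frozen=True)
class DiseaseMapping:
    """All detectors for one panel disease, keyed by its MeSH DUI."""

    dui: str
    name: str
    icd: tuple[IcdPattern, ...] = ()
    atc: tuple[AtcPattern, ...] = ()
    terms: tuple[TermPattern, ...] = ()

    def __post_init__(self) -> None:
        if not (self.icd or self.atc or self.terms):
            raise MappingError(f"disease {self.dui} ({self.name}) has no detector")


def parse_mapping_config(stream: TextIO | str) -> dict[str, DiseaseMapping]:
    """Load and validate a YAML/JSON mapping config.

    Schema::

        diseases:
          - dui: D003922
            name: Diabetes Mellitus, Type 1
            icd: ["E10*"]
            atc: ["A10A"]
            terms:
              - {pattern: '\\bdiab\\w+\\b', label: diabetes, fuzzy: false}

    Every pattern is validated and compiled; a disease with zero detectors
    is rejected.  Errors name the disease and the offending field.
    """
    if hasattr(stream, "read"):
        stream = stream.read()
    doc = yaml.safe_load(stream)
    if not isinstance(doc, dict) or "diseases" not in doc:
        raise MappingError("mapping config must contain a top-level 'diseases' list")
    out: dict[str, DiseaseMapping] = {}
    for entry in doc["diseases"]:
        dui = entry.get("dui", "<missing dui>")
        name = entry.get("name", dui)
        if dui in out:
            raise MappingError(f"duplicate disease mapping for {dui}")
        try:
            icd = tuple(IcdPattern.from_spec(s) for s in entry.get("icd", []) or [])
        except MappingError as exc:
            raise MappingError(f"{dui} ({name}), field icd: {exc}") from None
        try:
            atc = tuple(AtcPattern(str(s).rstrip("*")) for s in entry.get("atc", []) or [])
        except MappingError as exc:
            raise MappingError(f"{dui} ({name}), field atc: {exc}") from None
        terms = []
        for t in entry.get("terms", []) or []:
            if isinstance(t, str):
                t = {"pattern": t, "label": t}
            try:
                terms.append(
                    TermPattern(
                        pattern=t["pattern"],
                        label=t.get("label", t["pattern"]),
                        fuzzy=bool(t.get("fuzzy", False)),
                    )
                )
            except PatternError as exc:
                raise MappingError(f"{dui} ({name}), field terms: {exc}") from None
        try:
            out[dui] = DiseaseMapping(dui=dui, name=name, icd=icd, atc=atc, terms=tuple(terms))
        except MappingError as exc:
            raise MappingError(str(exc)) from None
    return out


def serialize_mapping_config(mappings: dict[str, DiseaseMapping]) -> str:
    """Inverse of :func:`parse_mapping_config` (round-trip stable)."""
    doc = {
        "diseases": [
            {
                "dui": m.dui,
                "name": m.name,
                "icd": [p.to_spec() for p in m.icd],
                "atc": [p.prefix for p in m.atc],
                "terms": [
                    {"pattern": t.pattern, "label": t.label, "fuzzy": t.fuzzy}
                    for t in m.terms
                ],
            }
            for m in mappings.values()
        ]
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
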