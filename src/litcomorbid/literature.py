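"""Literature-side inputs: MeSH descriptors and MEDLINE co-occurrence counts.

The comorbidity panel of an index disease is built in three steps:

1. parse the descriptor table (DUI, preferred name, tree numbers) and the
   pairwise co-occurrence counts;
2. restrict candidate partners to a hierarchy subtree (e.g. the autoimmune
   disease subtree ``C20.111``);
3. rank partners of the index descriptor by citation count and keep the
   top *k*.

The co-occurrence dialect here is a simple canonical one (three delimited
columns); genuine NLM MRCOC releases are release-specific and must be
converted to this dialect first (see :func:`parse_cooccurrence`).
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .errors import ParseError

__all__ = [
    "MeshDescriptor",
    "CooccurrenceRecord",
    "ComorbidityPanel",
    "parse_descriptors",
    "parse_cooccurrence",
    "subtree_members",
    "rank_comorbidities",
]

DUI_RE = re.compile(r"^D\d+$")
TREE_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)*$")


@dataclass(frozen=True)
class MeshDescriptor:
    """A MeSH descriptor: stable identifier, preferred term, tree addresses."""

    dui: str
    name: str
    tree_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not DUI_RE.match(self.dui):
            raise ParseError(f"invalid descriptor identifier: {self.dui!r}")
        for t in self.tree_numbers:
            if not TREE_RE.match(t):
                raise ParseError(f"invalid tree number {t!r} for {self.dui}")


@dataclass(frozen=True)
class CooccurrenceRecord:
    """Unordered descriptor pair with its MEDLINE citation co-occurrence count.

    Pairs are canonicalized so that ``dui_a < dui_b`` lexicographically.
    """

    dui_a: str
    dui_b: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ParseError(f"negative co-occurrence count for {self.dui_a}/{self.dui_b}")
        if self.dui_a >= self.dui_b:
            raise ParseError(
                f"pair not canonicalized: {self.dui_a!r} must sort before {self.dui_b!r}"
            )

    @staticmethod
    def make(dui_a: str, dui_b: str, count: int) -> "CooccurrenceRecord":
        """Build a canonical record from an arbitrarily ordered pair."""
        a, b = sorted((dui_a, dui_b))
        if a == b:
            raise ParseError(f"self-pair {a!r} is not a co-occurrence")
        return CooccurrenceRecord(a, b, int(count))

    def partner_of(self, dui: str) -> str | None:
        if dui == self.dui_a:
            return self.dui_b
        if dui == self.dui_b:
            return self.dui_a
        return None


@dataclass(frozen=True)
class ComorbidityPanel:
    """Top-k co-occurrence partners of the index disease within a subtree."""

    index_dui: str
    members: tuple[tuple[str, int], ...]
    subtree_root: str
    k: int

    def __post_init__(self) -> None:
        counts = [c for _, c in self.members]
        if counts != sorted(counts, reverse=True):
            raise ValueError("panel members must be sorted by count descending")
        if any(d == self.index_dui for d, _ in self.members):
            raise ValueError("index disease cannot be its own comorbidity")

    @property
    def duis(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.members, columns=["dui", "n_cooccurrence"])


def _read_delimited(stream: TextIO | str, required: list[str]) -> pd.DataFrame:
    """Read a small pipe- or tab-delimited table, auto-detecting the delimiter."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    if not text.strip():
        return pd.DataFrame(columns=required)
    header = text.splitlines()[0]
    sep = "|" if header.count("|") >= header.count("\t") and "|" in header else "\t"
    if "|" not in header and "\t" not in header:
        raise ParseError(f"cannot detect delimiter in header {header!r}")
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s) {missing}; found {list(df.columns)}")
    for c in df.columns:
        df[c] = df[c].astype(str).str.strip()
    return df


def parse_descriptors(stream: TextIO | str) -> dict[str, MeshDescriptor]:
    """Parse a descriptor table into a DUI-keyed mapping.

    Expected columns: ``dui``, ``name``, ``tree_numbers`` (semicolon-joined).
    Duplicate DUIs and malformed identifiers or tree numbers are rejected,
    naming the offending line.
    """
    df = _read_delimited(stream, ["dui", "name", "tree_numbers"])
    out: dict[str, MeshDescriptor] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        dui = row.dui
        if dui in out:
            raise ParseError(f"line {i}: duplicate descriptor identifier {dui!r}")
        trees = tuple(t.strip() for t in row.tree_numbers.split(";") if t.strip())
        try:
            out[dui] = MeshDescriptor(dui, row.name, trees)
        except ParseError as exc:
            raise ParseError(f"line {i}: {exc}") from None
    return out


def parse_cooccurrence(stream: TextIO | str) -> list[CooccurrenceRecord]:
    """Parse co-occurrence counts; pairs are canonicalized as unordered.

    Expected columns ``dui_a``, ``dui_b``, ``count``; an optional ``year``
    column is accepted and ignored.  Duplicate rows for the same unordered
    pair are summed with a warning.
    """
    df = _read_delimited(stream, ["dui_a", "dui_b", "count"])
    totals: dict[tuple[str, str], int] = {}
    dup = False
    for i, row in enumerate(df.itertuples(index=False), start=2):
        for d in (row.dui_a, row.dui_b):
            if not DUI_RE.match(d):
                raise ParseError(f"line {i}: invalid descriptor identifier {d!r}")
        try:
            n = int(row.count)
        except ValueError:
            raise ParseError(f"line {i}: non-integer count {row.count!r}") from None
        if n < 0:
            raise ParseError(f"line {i}: negative count {n}")
        key = tuple(sorted((row.dui_a, row.dui_b)))
        if key[0] == key[1]:
            raise ParseError(f"line {i}: self-pair {key[0]!r}")
        if key in totals:
            dup = True
        totals[key] = totals.get(key, 0) + n
    if dup:
        warnings.warn("duplicate unordered pairs found; counts were summed", stacklevel=2)
    return [CooccurrenceRecord(a, b, c) for (a, b), c in totals.items()]


def tree_in_subtree(tree: str, root_prefix: str) -> bool:
    """True iff *tree* equals the root or is a descendant of it.

    Tree numbers are positional addresses, so the prefix must respect node
    (dot) boundaries: ``C20.111`` matches ``C20.111`` and ``C20.111.199``
    but never ``C20.1115``.
    """
    return tree == root_prefix or tree.startswith(root_prefix + ".")


def subtree_members(
    descriptors: Mapping[str, MeshDescriptor] | Iterable[MeshDescriptor],
    root_prefix: str,
) -> set[str]:
    """DUIs of descriptors having at least one tree number in the subtree."""
    if not TREE_RE.match(root_prefix):
        raise ParseError(f"invalid tree-number prefix {root_prefix!r}")
    if isinstance(descriptors, Mapping):
        descriptors = descriptors.values()
    return {
        d.dui
        for d in descriptors
        if any(tree_in_subtree(t, root_prefix) for t in d.tree_numbers)
    }


def rank_comorbidities(
    records: Iterable[CooccurrenceRecord],
    index_dui: str,
    allowed: set[str],
    k: int,
    subtree_root: str = "",
) -> ComorbidityPanel:
    """Select the k highest-count co-occurrence partners of the index disease.

    Partners are restricted to *allowed* (normally the subtree members) and
    sorted by count descending, ties broken by DUI for a deterministic
    display order.  A tie exactly at rank *k* is never truncated
    arbitrarily: all tied members are kept (panel may exceed *k*) and a
    warning is emitted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals: dict[str, int] = {}
    for rec in records:
        partner = rec.partner_of(index_dui)
        if partner is None or partner == index_dui or partner not in allowed:
            continue
        totals[partner] = totals.get(partner, 0) + rec.count
    ranked = sorted(totals.items(), key=lambda item: (-item[1], item[0]))
    if len(ranked) > k:
        cutoff = ranked[k - 1][1]
        kept = [m for m in ranked if m[1] > cutoff]
        tied = [m for m in ranked if m[1] == cutoff]
        members = kept + tied
        if len(members) > k:
            warnings.warn(
                f"{len(tied)} partners tied at rank {k} (count {cutoff}); "
                f"panel extended to {len(members)} members",
                stacklevel=2,
            )
    else:
        members = ranked
    return ComorbidityPanel(
        index_dui=index_dui,
        members=tuple(members),
        subtree_root=subtree_root,
        k=k,
    )
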