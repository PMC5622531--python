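"""Accent folding with an offset map back to the original text.

Clinical text in the source EHR is French; detectors run over accent-folded
text (``thyroïdite`` → ``thyroidite``, ``œ`` → ``oe``) so that patterns can
be written without diacritics.  Folding may change string length (ligature
expansion), so a per-character map from folded offsets to original offsets
is kept for span reporting.
"""

from __future__ import annotations

import unicodedata

__all__ = ["fold_text", "levenshtein_leq1"]

_LIGATURES = {"œ": "oe", "Œ": "OE", "æ": "ae", "Æ": "AE", "ß": "ss"}


def fold_text(text: str) -> tuple[str, list[int]]:
    """Return (folded text, map folded index → original index).

    Each original character decomposes (NFKD) into its base character(s);
    combining marks are dropped.  Every folded character maps back to the
    index of the original character it came from.
    """
    out: list[str] = []
    offsets: list[int] = []
    for i, ch in enumerate(text):
        if ch in _LIGATURES:
            repl = _LIGATURES[ch]
        else:
            repl = "".join(
                c for c in unicodedata.normalize("NFKD", ch) if not unicodedata.combining(c)
            )
            if not repl:  # lone combining mark: drop
                continue
        out.append(repl)
        offsets.extend([i] * len(repl))
    return "".join(out), offsets


def levenshtein_leq1(a: str, b: str) -> bool:
    """True iff edit distance between *a* and *b* is at most 1.

    Thin wrapper over edlib when available; a direct two-string check
    otherwise (the distance-1 case needs no DP table).
    """
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    try:
        import edlib

        return edlib.align(a, b, k=1)["editDistance"] != -1
    except ImportError:  # pragma: no cover - edlib is a declared dependency
        if la == lb:
            return sum(x != y for x, y in zip(a, b)) <= 1
        if la > lb:
            a, b, la, lb = b, a, lb, la
        i = 0
        while i < la and a[i] == b[i]:
            i += 1
        return a[i:] == b[i + 1 :]
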