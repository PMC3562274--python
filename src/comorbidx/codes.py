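"""ICD-10-AM diagnosis-code handling.

Victorian hospital-episode data attach a prefix to every ICD-10-AM code:
``P`` (principal diagnosis), ``A`` (additional diagnosis) or ``C``
(in-hospital complication).  This module provides the canonical dotless
code form, WHO chapter assignment, inclusive code-range membership, and
the selection rules that decide which of an admission's codes count as
*comorbidities*:

i.   all ``C``-prefixed codes are dropped (in-hospital complications);
ii.  ``P``-prefixed Chapter XIX codes are dropped (the injury itself);
iii. all Chapter XVIII codes are dropped (symptoms and signs);
iv.  Chapters XX-XXII are dropped (external causes / special purposes);
v.   codes on an editable blocklist of erroneously coded acute
     complications (e.g. acute post-haemorrhagic anaemia) are dropped.

Codes are stored dotless and uppercase ("M80.0" -> "M800"): one letter
followed by two to four digits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CodeError",
    "DiagnosisCode",
    "CodeRange",
    "canonicalize_code",
    "assign_chapter",
    "in_range",
    "select_comorbidity_codes",
    "load_chapter_bands",
    "load_blocklist",
    "CHAPTER_IDS",
    "COMORBIDITY_CHAPTERS",
    "PREFIXES",
]

_CODE_RE = re.compile(r"^[A-Z][0-9]{2,4}$")

PREFIXES = ("P", "A", "C")


class CodeError(ValueError):
    """Raised for malformed ICD-10 codes, ranges or prefixes."""


def canonicalize_code(raw: str) -> str:
    """Return the canonical dotless uppercase form of an ICD-10 code.

    >>> canonicalize_code("M80.0")
    'M800'
    >>> canonicalize_code("i21")
    'I21'

    Raises :class:`CodeError` if the input does not reduce to a letter
    followed by 2-4 digits.  Idempotent on canonical input.
    """
    if raw is None or not str(raw).strip():
        raise CodeError("empty ICD-10 code")
    s = str(raw).strip().upper()
    if "." in s and not re.match(r"^[A-Z][0-9]{2}\.[0-9]{1,2}$", s):
        raise CodeError(f"malformed ICD-10 code: {raw!r}")
    code = s.replace(".", "")
    if not _CODE_RE.match(code):
        raise CodeError(f"malformed ICD-10 code: {raw!r}")
    return code


@dataclass(frozen=True)
class DiagnosisCode:
    """A single prefixed ICD-10-AM diagnosis code."""

    prefix: str
    code: str

    def __post_init__(self) -> None:
        if self.prefix not in PREFIXES:
            raise CodeError(f"prefix must be one of {PREFIXES}, got {self.prefix!r}")
        object.__setattr__(self, "code", canonicalize_code(self.code))


@dataclass(frozen=True)
class CodeRange:
    """An inclusive ICD-10 code range as printed in a mapping table.

    Endpoints set the granularity: a range printed at 3 characters
    ("I21-I24") contains any code whose 3-character truncation lies in
    the band; a 4-character range ("M05.0-M05.9" -> M050-M059) matches
    on the 4-character form, and a shorter input code matches iff some
    digit-extension of it does.  ``exact=True`` restricts matching to
    the literal code (used where a table lists a bare 3-character code
    next to 4th-character subdivisions it must not absorb).
    """

    low: str
    high: str
    exact: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "low", canonicalize_code(self.low))
        object.__setattr__(self, "high", canonicalize_code(self.high))
        if len(self.low) != len(self.high):
            raise CodeError(f"range endpoints differ in granularity: {self.low}-{self.high}")
        if self.low > self.high:
            raise CodeError(f"range low above high: {self.low}-{self.high}")

    @classmethod
    def parse(cls, span: str, exact: bool = False) -> "CodeRange":
        """Parse a printed span like ``"M05.0-M05.9"`` or ``"I25.2"``."""
        parts = [p.strip() for p in str(span).split("-")]
        if len(parts) == 1:
            return cls(parts[0], parts[0], exact=exact)
        if len(parts) == 2:
            return cls(parts[0], parts[1], exact=exact)
        raise CodeError(f"cannot parse code range: {span!r}")

    @property
    def granularity(self) -> int:
        return len(self.low)

    def contains(self, code: str) -> bool:
        return in_range(code, self)


def in_range(code: str, rng: CodeRange) -> bool:
    """True iff ``code`` (canonical) falls in ``rng`` under its granularity."""
    if rng.exact:
        return code == rng.low
    g = rng.granularity
    if len(code) >= g:
        c = code[:g]
        return rng.low <= c <= rng.high
    # shorter code: matches iff some digit-extension would
    pad = g - len(code)
    return not (code + "9" * pad < rng.low or code + "0" * pad > rng.high)


# ---------------------------------------------------------------------------
# WHO chapter bands

CHAPTER_IDS = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
    "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
    "XXI", "XXII",
)

#: chapters that can hold a comorbidity after the selection rules
COMORBIDITY_CHAPTERS = CHAPTER_IDS[:17] + ("XIX",)


def _data_path(name: str):
    return resources.files("comorbidx.data").joinpath(name)


def load_chapter_bands(path=None) -> pd.DataFrame:
    """Chapter band table: columns chapter, low, high, label."""
    src = path if path is not None else _data_path("chapter_bands.csv")
    df = pd.read_csv(src, dtype=str)
    df["low"] = df["low"].map(canonicalize_code)
    df["high"] = df["high"].map(canonicalize_code)
    return df


_BANDS_CACHE: list[tuple[str, str, str]] | None = None


def _chapter_bands() -> list[tuple[str, str, str]]:
    global _BANDS_CACHE
    if _BANDS_CACHE is None:
        df = load_chapter_bands()
        _BANDS_CACHE = list(zip(df["chapter"], df["low"], df["high"]))
    return _BANDS_CACHE


def assign_chapter(code: str) -> str:
    """Return the ICD-10 chapter id (roman numeral) containing ``code``.

    The code is compared at 3-character resolution against the WHO
    chapter bands.  Codes in gaps between bands (e.g. D49, which is
    unused in ICD-10) raise :class:`CodeError`.
    """
    c3 = canonicalize_code(code)[:3]
    for chap, low, high in _chapter_bands():
        if low <= c3 <= high:
            return chap
    raise CodeError(f"code {code!r} lies outside every ICD-10 chapter band")


# ---------------------------------------------------------------------------
# Erroneous-complication blocklist

def load_blocklist(path=None) -> list[CodeRange]:
    """Load the acute-complication blocklist (editable CSV of spans)."""
    src = path if path is not None else _data_path("blocklist.csv")
    df = pd.read_csv(src, dtype=str, comment="#")
    out: list[CodeRange] = []
    for _, row in df.iterrows():
        for span in str(row["spans"]).split(";"):
            out.append(CodeRange.parse(span))
    return out


def _blocked(code: str, blocklist: Sequence[CodeRange]) -> bool:
    return any(in_range(code, r) for r in blocklist)


def select_comorbidity_codes(
    diagnoses: Iterable[DiagnosisCode | tuple[str, str]],
    blocklist: Sequence[CodeRange] | None = None,
) -> list[str]:
    """Apply the comorbidity selection rules to one admission's codes.

    Parameters
    ----------
    diagnoses
        ``DiagnosisCode`` objects or ``(prefix, code)`` pairs.
    blocklist
        Erroneous-complication ranges; defaults to the packaged list.

    Returns the surviving canonical codes, deduplicated, in first-seen
    order.  Output is always a subset of the input codes.
    """
    if blocklist is None:
        blocklist = load_blocklist()
    seen: dict[str, None] = {}
    for d in diagnoses:
        if not isinstance(d, DiagnosisCode):
            d = DiagnosisCode(*d)
        if d.prefix == "C":
            continue
        chap = assign_chapter(d.code)
        if chap == "XIX" and d.prefix == "P":
            continue
        if chap == "XVIII" or chap in ("XX", "XXI", "XXII"):
            continue
        if _blocked(d.code, blocklist):
            continue
        seen.setdefault(d.code, None)
    return list(seen)
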