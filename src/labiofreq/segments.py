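"""Segment alphabets and tokenization for phonetically transcribed word lists.

Word lists in the ASJP tradition are written in "ASJPcode", a restricted
computationally friendly alphabet: 7 vowel symbols, 34 consonant symbols, and
two modifier symbols (``~`` binds the preceding two symbols into one sound,
``$`` the preceding three).  For the purpose of counting consonant tokens,
bound sequences such as prenasalized stops are counted as separate consonants,
so tokenization simply drops the modifiers and keeps the bound symbols.

The alphabet is data, not code: a :class:`SegmentClassTable` is loaded from a
CSV resource (columns ``symbol,class,subclass``) so that encoding dialects can
be accommodated without touching the tokenizer.  Two tables ship with the
package: ``asjp`` (word lists) and ``ipa`` (pre-tokenized text ingestion,
where the labiodental class additionally contains ʋ, ɱ and ⱱ).
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable

__all__ = [
    "SegmentClassTable",
    "TokenizationError",
    "tokenize",
    "detokenize",
    "classify_segment",
    "is_labiodental",
]


class TokenizationError(ValueError):
    """A transcription contains a symbol outside the segment-class table.

    Carries the offending ``symbol`` and its 0-based ``offset`` in the raw
    string; usually signals an encoding-dialect mismatch rather than bad data.
    """

    def __init__(self, symbol: str, offset: int, raw: str):
        self.symbol = symbol
        self.offset = offset
        self.raw = raw
        super().__init__(
            f"unknown segment symbol {symbol!r} at offset {offset} in {raw!r}; "
            "not in the segment-class table (vowels, consonants, modifiers or "
            "ignorable symbols) - check the encoding dialect"
        )


@dataclass(frozen=True)
class SegmentClassTable:
    """Partition of an alphabet into vowels, consonants, modifiers and ignorables.

    ``labiodentals`` must be a subset of ``consonants``; the four symbol
    classes must be pairwise disjoint.
    """

    vowels: frozenset[str]
    consonants: frozenset[str]
    labiodentals: frozenset[str]
    modifiers: frozenset[str] = field(default_factory=frozenset)
    ignorable: frozenset[str] = field(default_factory=frozenset)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.labiodentals <= self.consonants:
            raise ValueError("labiodentals must be a subset of consonants")
        classes = [self.vowels, self.consonants, self.modifiers, self.ignorable]
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                overlap = a & b
                if overlap:
                    raise ValueError(f"segment classes overlap on {sorted(overlap)!r}")

    @property
    def segments(self) -> frozenset[str]:
        """All countable segment symbols (vowels plus consonants)."""
        return self.vowels | self.consonants

    @classmethod
    def from_rows(cls, rows: Iterable[dict], name: str = "") -> "SegmentClassTable":
        vowels, consonants, labiodentals = set(), set(), set()
        modifiers, ignorable = set(), set()
        for row in rows:
            sym = row["symbol"]
            klass = row["class"].strip().lower()
            sub = (row.get("subclass") or "").strip().lower()
            if klass == "vowel":
                vowels.add(sym)
            elif klass == "consonant":
                consonants.add(sym)
                if sub == "labiodental":
                    labiodentals.add(sym)
            elif klass == "modifier":
                modifiers.add(sym)
            elif klass == "ignorable":
                ignorable.add(sym)
            else:
                raise ValueError(f"unknown segment class {klass!r} for symbol {sym!r}")
        return cls(
            vowels=frozenset(vowels),
            consonants=frozenset(consonants),
            labiodentals=frozenset(labiodentals),
            modifiers=frozenset(modifiers),
            ignorable=frozenset(ignorable),
            name=name,
        )

    @classmethod
    def from_csv(cls, path, name: str = "") -> "SegmentClassTable":
        with open(path, encoding="utf-8", newline="") as fh:
            return cls.from_rows(csv.DictReader(fh), name=name or str(path))

    @classmethod
    def default(cls, dialect: str = "asjp") -> "SegmentClassTable":
        """The packaged table for ``dialect`` (``"asjp"`` or ``"ipa"``)."""
        return _load_packaged_table(dialect)


@lru_cache(maxsize=None)
def _load_packaged_table(dialect: str) -> SegmentClassTable:
    fname = {"asjp": "asjp_segments.csv", "ipa": "ipa_segments.csv"}.get(dialect)
    if fname is None:
        raise ValueError(f"no packaged segment table for dialect {dialect!r}")
    ref = resources.files("labiofreq").joinpath("data", fname)
    with ref.open(encoding="utf-8", newline="") as fh:
        return SegmentClassTable.from_rows(csv.DictReader(fh), name=dialect)


def tokenize(raw: str, classes: SegmentClassTable | None = None) -> list[str]:
    """Split a transcription into segment symbols.

    Modifier symbols (cluster binders, diacritics) and ignorable symbols
    (spacing, loan markers) are dropped; every symbol they bound is retained
    as its own segment, so e.g. a prenasalized cluster written ``"nd~o"``
    tokenizes to ``[n, d, o]`` and contributes two consonant tokens.

    Raises :class:`TokenizationError` for a symbol in none of the classes.
    """
    if classes is None:
        classes = SegmentClassTable.default("asjp")
    segments = classes.segments
    skip = classes.modifiers | classes.ignorable
    # decompose precomposed characters so diacritics match the modifier set
    raw = unicodedata.normalize("NFD", raw)
    out: list[str] = []
    for offset, sym in enumerate(raw):
        if sym in skip:
            continue
        if sym in segments:
            out.append(sym)
        else:
            raise TokenizationError(sym, offset, raw)
    return out


def detokenize(tokens: Iterable[str]) -> str:
    """Inverse of :func:`tokenize` on modifier-free transcriptions."""
    return "".join(tokens)


def classify_segment(symbol: str, classes: SegmentClassTable | None = None) -> str:
    """Return ``"vowel"`` or ``"consonant"`` for a segment symbol."""
    if classes is None:
        classes = SegmentClassTable.default("asjp")
    if symbol in classes.consonants:
        return "consonant"
    if symbol in classes.vowels:
        return "vowel"
    raise TokenizationError(symbol, 0, symbol)


def is_labiodental(symbol: str, classes: SegmentClassTable | None = None) -> bool:
    """True iff ``symbol`` is a labiodental consonant under ``classes``."""
    if classes is None:
        classes = SegmentClassTable.default("asjp")
    if symbol not in classes.segments:
        raise TokenizationError(symbol, 0, symbol)
    return symbol in classes.labiodentals
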