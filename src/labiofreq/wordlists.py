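"""Word-list containers and readers.

The unit of analysis is the *doculect*: one documented language variety,
represented by a word list of 40-100 basic concepts in a phonetic encoding.
Two tabular dialects are read:

``long``
    CLDF-style long table, one row per transcription, with columns
    ``doculect_id, concept_id, transcription`` and optional ``name``,
    ``iso_code``, ``glottocode`` columns (constant within a doculect).

``wide``
    One row per doculect; identifier columns followed by one column per
    concept holding the transcription.

Comma-separated synonym variants in a transcription cell become separate
:class:`WordForm` entries with incremented ``variant_index``; all variants
are counted in the downstream statistics.  Missing-entry placeholders
(empty cell, ``XXX`` or ``?``) produce no form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .segments import SegmentClassTable, TokenizationError, tokenize

__all__ = ["WordForm", "Doculect", "ParseIssue", "WordlistParseError", "parse_wordlist_file"]

MISSING_PLACEHOLDERS = frozenset({"", "XXX", "?", "NA"})

ID_COLUMNS = ("doculect_id", "name", "iso_code", "glottocode")


@dataclass(frozen=True)
class WordForm:
    """One transcription variant of one concept."""

    concept_id: str
    variant_index: int
    raw: str
    tokens: tuple[str, ...]


@dataclass
class Doculect:
    """A word list plus identifiers; hooks for metadata joins."""

    doculect_id: str
    name: str = ""
    iso_code: str | None = None
    glottocode: str | None = None
    forms: list[WordForm] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doculect_id:
            raise ValueError("doculect_id must be non-empty")


@dataclass(frozen=True)
class ParseIssue:
    """A recoverable record-level problem, reported with its source line."""

    line: int
    message: str


class WordlistParseError(ValueError):
    """Unrecoverable word-list problem (e.g. duplicated variant rows)."""


def _is_missing(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return True
    return str(value).strip() in MISSING_PLACEHOLDERS


def _split_variants(cell: str) -> list[str]:
    return [v.strip() for v in str(cell).split(",") if v.strip() not in MISSING_PLACEHOLDERS]


def parse_wordlist_file(
    source,
    dialect: str = "long",
    classes: SegmentClassTable | None = None,
    sep: str = ",",
    on_error: str = "collect",
) -> tuple[list[Doculect], list[ParseIssue]]:
    """Read a word-list table into :class:`Doculect` objects.

    Parameters
    ----------
    source
        Path, file-like object, or literal CSV text.
    dialect
        ``"long"`` (CLDF-style) or ``"wide"`` (one concept per column).
    classes
        Segment-class table used to tokenize; defaults to the ASJP table.
    on_error
        ``"collect"`` records row-level issues (untokenizable transcriptions,
        rows with missing keys) and drops the affected form; ``"raise"``
        re-raises immediately.  Duplicate (doculect, concept, transcription)
        rows are always a hard :class:`WordlistParseError`.

    Returns
    -------
    (doculects, issues)
    """
    if classes is None:
        classes = SegmentClassTable.default("asjp")
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)

    if dialect == "long":
        records = _iter_long(frame)
    elif dialect == "wide":
        records = _iter_wide(frame)
    else:
        raise ValueError(f"unknown word-list dialect {dialect!r}")

    issues: list[ParseIssue] = []
    doculects: dict[str, Doculect] = {}
    variant_counter: dict[tuple[str, str], int] = {}
    seen: set[tuple[str, str, str]] = set()

    for line, ident, concept, cell in records:
        if not ident["doculect_id"] or not concept:
            issue = ParseIssue(line, "row lacks doculect_id or concept_id")
            if on_error == "raise":
                raise WordlistParseError(f"line {line}: {issue.message}")
            issues.append(issue)
            continue
        doc = doculects.get(ident["doculect_id"])
        if doc is None:
            doc = Doculect(
                doculect_id=ident["doculect_id"],
                name=ident.get("name") or ident["doculect_id"],
                iso_code=ident.get("iso_code") or None,
                glottocode=ident.get("glottocode") or None,
            )
            doculects[doc.doculect_id] = doc
        if _is_missing(cell):
            continue
        for raw in _split_variants(cell):
            key = (doc.doculect_id, concept, raw)
            if key in seen:
                raise WordlistParseError(
                    f"line {line}: duplicate variant {raw!r} for "
                    f"({doc.doculect_id!r}, {concept!r})"
                )
            seen.add(key)
            try:
                tokens = tuple(tokenize(raw, classes))
            except TokenizationError as exc:
                if on_error == "raise":
                    raise
                issues.append(ParseIssue(line, f"{doc.doculect_id}/{concept}: {exc}"))
                continue
            idx = variant_counter.get((doc.doculect_id, concept), 0)
            variant_counter[(doc.doculect_id, concept)] = idx + 1
            doc.forms.append(
                WordForm(concept_id=concept, variant_index=idx, raw=raw, tokens=tokens)
            )
    return list(doculects.values()), issues


def _iter_long(frame: pd.DataFrame):
    required = {"doculect_id", "concept_id", "transcription"}
    missing = required - set(frame.columns)
    if missing:
        raise WordlistParseError(f"long table lacks columns {sorted(missing)}")
    for i, row in enumerate(frame.to_dict("records"), start=2):
        ident = {c: row.get(c, "") for c in ID_COLUMNS}
        yield i, ident, str(row["concept_id"]).strip(), row["transcription"]


def _iter_wide(frame: pd.DataFrame):
    if "doculect_id" not in frame.columns:
        raise WordlistParseError("wide table lacks a doculect_id column")
    concept_cols = [c for c in frame.columns if c not in ID_COLUMNS]
    if not concept_cols:
        raise WordlistParseError("wide table has no concept columns")
    for i, row in enumerate(frame.to_dict("records"), start=2):
        ident = {c: row.get(c, "") for c in ID_COLUMNS}
        for concept in concept_cols:
            yield i, ident, concept, row[concept]
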