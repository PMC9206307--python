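"""Phrase lexicons driving the theme and change filters.

A lexicon maps surface phrases to either an outcome theme (with a ±1
sentiment polarity) or to the special ``change`` category (with a ±1
direction: +1 = increase, −1 = decrease).  Phrases are stored case-folded,
NFC-normalized and whitespace-collapsed; matching against a token stream is
exact on surfaces by default, with an optional lemma mode.
"""

from __future__ import annotations

import csv
import json
import unicodedata
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CHANGE_CATEGORY",
    "DEFAULT_THEMES",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "save_lexicon",
    "expand_variants",
    "lookup",
    "find_phrase_occurrences",
    "normalize_phrase",
]

CHANGE_CATEGORY = "change"

#: The four transdiagnostic outcome themes: symptom reduction, social
#: functioning, general well-being and patient experience.
DEFAULT_THEMES = ("symptoms", "social", "wellbeing", "experience")

_MATCH_MODES = ("exact-token", "lemma")


class LexiconError(ValueError):
    """Raised for malformed lexicon files or invalid entries."""


def normalize_phrase(phrase: str) -> str:
    """Case-fold, NFC-normalize and collapse internal whitespace."""
    return " ".join(unicodedata.normalize("NFC", phrase).casefold().split())


@dataclass(frozen=True)
class LexiconEntry:
    """One matchable phrase bound to a theme (or to "change") with a sign.

    For theme entries ``polarity`` is the sentiment connotation; for change
    entries it is the direction of change (+1 increase, −1 decrease).
    """

    phrase: str
    category: str  # "theme:<name>" or "change"
    polarity: int  # −1 or +1
    match_mode: str = "exact-token"

    def __post_init__(self) -> None:
        normalized = normalize_phrase(self.phrase)
        if not normalized:
            raise LexiconError("lexicon phrase is empty after normalization")
        object.__setattr__(self, "phrase", normalized)
        if self.polarity not in (-1, 1):
            raise LexiconError(
                f"polarity must be -1 or +1, got {self.polarity!r} for {self.phrase!r}"
            )
        if self.category != CHANGE_CATEGORY and not (
            self.category.startswith("theme:") and self.category[6:]
        ):
            raise LexiconError(
                f"category must be 'change' or 'theme:<name>', got {self.category!r}"
            )
        if self.match_mode not in _MATCH_MODES:
            raise LexiconError(
                f"match_mode must be one of {_MATCH_MODES}, got {self.match_mode!r}"
            )

    @property
    def theme(self) -> str | None:
        """Theme name, or None for change entries."""
        if self.category == CHANGE_CATEGORY:
            return None
        return self.category.split(":", 1)[1]

    @property
    def is_change(self) -> bool:
        return self.category == CHANGE_CATEGORY

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.phrase.split())


@dataclass(frozen=True)
class Lexicon:
    """A validated collection of lexicon entries plus its theme inventory.

    Equality ignores entry order, so loading a shuffled copy of the same
    file yields an equal lexicon.
    """

    entries: tuple[LexiconEntry, ...]
    themes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        seen: set[tuple[str, str]] = set()
        for entry in entries:
            key = (entry.phrase, entry.category)
            if key in seen:
                raise LexiconError(
                    f"duplicate lexicon entry for phrase {entry.phrase!r} "
                    f"in category {entry.category!r}"
                )
            seen.add(key)
        themes = tuple(self.themes)
        if not themes:
            themes = tuple(sorted({e.theme for e in entries if e.theme is not None}))
        else:
            missing = {e.theme for e in entries if e.theme} - set(themes)
            if missing:
                raise LexiconError(f"entries reference undeclared themes: {sorted(missing)}")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "themes", themes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return set(self.entries) == set(other.entries) and set(self.themes) == set(
            other.themes
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.entries), frozenset(self.themes)))

    def theme_entries(self, theme: str | None = None) -> tuple[LexiconEntry, ...]:
        if theme is None:
            return tuple(e for e in self.entries if not e.is_change)
        return tuple(e for e in self.entries if e.theme == theme)

    def change_entries(self) -> tuple[LexiconEntry, ...]:
        return tuple(e for e in self.entries if e.is_change)

    def restrict_to_theme(self, theme: str) -> "Lexicon":
        """Lexicon containing only one theme's entries plus all change entries."""
        kept = tuple(e for e in self.entries if e.is_change or e.theme == theme)
        return Lexicon(entries=kept, themes=(theme,))

    def without_phrase(self, phrase: str, category: str) -> "Lexicon":
        norm = normalize_phrase(phrase)
        kept = tuple(
            e for e in self.entries if not (e.phrase == norm and e.category == category)
        )
        return Lexicon(entries=kept, themes=self.themes)


def _entry_from_record(record: dict, where: str) -> LexiconEntry:
    for key in ("phrase", "category", "polarity"):
        if key not in record or record[key] in (None, ""):
            raise LexiconError(f"{where}: missing required field {key!r}")
    try:
        polarity = int(str(record["polarity"]).replace("+", ""))
    except ValueError as exc:
        raise LexiconError(f"{where}: polarity {record['polarity']!r} is not an integer") from exc
    try:
        return LexiconEntry(
            phrase=str(record["phrase"]),
            category=str(record["category"]).strip(),
            polarity=polarity,
            match_mode=str(record.get("match_mode") or "exact-token").strip(),
        )
    except LexiconError as exc:
        raise LexiconError(f"{where}: {exc}") from exc


def load_lexicon(path: str | Path, format: str | None = None) -> Lexicon:
    """Load a lexicon from a TSV (phrase/category/polarity[/match_mode]) or JSON file.

    Loading is order-independent: the same rows in any order produce an
    equal :class:`Lexicon`.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    entries: list[LexiconEntry] = []
    if fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise LexiconError(f"{path}: JSON lexicon must be an array of objects")
        for i, record in enumerate(records):
            entries.append(_entry_from_record(record, f"{path} entry {i}"))
    elif fmt == "tsv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                return Lexicon(entries=())
            required = {"phrase", "category", "polarity"}
            if not required.issubset(reader.fieldnames):
                raise LexiconError(
                    f"{path}: header must contain {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for row_number, row in enumerate(reader, start=2):
                entries.append(_entry_from_record(row, f"{path} row {row_number}"))
    else:
        raise LexiconError(f"unknown lexicon format {fmt!r}")
    return Lexicon(entries=tuple(entries))


def save_lexicon(lexicon: Lexicon, path: str | Path, format: str | None = None) -> None:
    """Write a lexicon; round-trips bit-stably (entries sorted, normalized)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    ordered = sorted(lexicon.entries, key=lambda e: (e.category, e.phrase))
    if fmt == "json":
        payload = [
            {
                "phrase": e.phrase,
                "category": e.category,
                "polarity": e.polarity,
                "match_mode": e.match_mode,
            }
            for e in ordered
        ]
        path.write_text(json.dumps(payload, ensure_ascii=False, indent=1) + "\n", "utf-8")
    elif fmt == "tsv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["phrase", "category", "polarity", "match_mode"])
            for e in ordered:
                writer.writerow([e.phrase, e.category, e.polarity, e.match_mode])
    else:
        raise LexiconError(f"unknown lexicon format {fmt!r}")


def expand_variants(entry: LexiconEntry, variants: Sequence[str]) -> list[LexiconEntry]:
    """Clone an entry under alternative surface forms (misspellings, inflections).

    Variants that normalize to the base phrase are skipped with a warning.
    """
    if not variants:
        raise LexiconError("variants must be non-empty")
    clones: list[LexiconEntry] = []
    seen: set[str] = set()
    for variant in variants:
        norm = normalize_phrase(variant)
        if norm == entry.phrase:
            warnings.warn(
                f"variant {variant!r} equals base phrase {entry.phrase!r}; skipped",
                stacklevel=2,
            )
            continue
        if not norm or norm in seen:
            continue
        seen.add(norm)
        clones.append(replace(entry, phrase=norm))
    return clones


def _token_forms(token) -> tuple[str, str]:
    """Accept (surface, lemma) pairs or objects with .surface/.lemma."""
    if isinstance(token, tuple):
        surface, lemma = token
    else:
        surface, lemma = token.surface, token.lemma
    return normalize_phrase(surface), normalize_phrase(lemma)


def find_phrase_occurrences(
    tokens: Sequence, phrase_tokens: Sequence[str], use_lemma: bool = False
) -> list[tuple[int, int]]:
    """All contiguous occurrences of a normalized phrase, as half-open token spans.

    Occurrences of a single phrase never overlap (greedy left-to-right scan).
    """
    forms = [_token_forms(t)[1 if use_lemma else 0] for t in tokens]
    width = len(phrase_tokens)
    spans: list[tuple[int, int]] = []
    if width == 0:
        return spans
    i = 0
    while i + width <= len(forms):
        if forms[i : i + width] == list(phrase_tokens):
            spans.append((i, i + width))
            i += width
        else:
            i += 1
    return spans


def lookup(
    lexicon: Lexicon, tokens: Sequence, entries: Iterable[LexiconEntry] | None = None
) -> list[tuple[tuple[int, int], LexiconEntry]]:
    """Match lexicon phrases against a token stream.

    Returns ``(span, entry)`` pairs, spans 0-based half-open over token
    indices.  Per entry, matches are maximal and non-overlapping; different
    entries may match overlapping spans and each contributes its own match.
    """
    hits: list[tuple[tuple[int, int], LexiconEntry]] = []
    for entry in entries if entries is not None else lexicon.entries:
        spans = find_phrase_occurrences(
            tokens, entry.tokens, use_lemma=(entry.match_mode == "lemma")
        )
        hits.extend((span, entry) for span in spans)
    hits.sort(key=lambda h: (h[0][0], h[0][1], h[1].category, h[1].phrase))
    return hits
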