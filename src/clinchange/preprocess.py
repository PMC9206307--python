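"""Sentence segmentation and token annotation.

Notes are split into sentences, and each token is annotated with a lemma, a
coarse POS tag, a morphological degree (for comparative-change detection)
and a dependency head/relation.  The downstream filters depend only on the
:class:`Token` contract, so the annotation backend is pluggable: any object
implementing :class:`Annotator` can be injected.  The shipped default is
:class:`RuleBasedAnnotator`, a deterministic suffix/table annotator with a
language-configurable comparative-suffix table, which produces a flat
dependency tree and declares ``provides_dependencies = False`` (the linkage
check then falls back to its token-window rule).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date as _date
from typing import Protocol, Sequence

__all__ = [
    "Note",
    "Token",
    "AnnotatedSentence",
    "Annotator",
    "RuleBasedAnnotator",
    "DegreeTable",
    "PreprocessError",
    "segment",
    "annotate_degree",
    "split_sentences",
]

DEGREE_POSITIVE = "positive"
DEGREE_COMPARATIVE = "comparative"
DEGREE_SUPERLATIVE = "superlative"
DEGREE_NA = "n/a"


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class Note:
    """One free-text clinical note with its provenance identifiers."""

    patient_id: str
    trajectory_id: str
    note_id: str
    date: _date
    text: str

    def __post_init__(self) -> None:
        for name in ("patient_id", "trajectory_id", "note_id"):
            if not getattr(self, name):
                raise PreprocessError(f"note field {name!r} must be non-empty")
        if not self.text.strip():
            raise PreprocessError(f"note {self.note_id!r} has empty text")


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str
    degree: str  # positive | comparative | superlative | n/a
    head: int  # index of governing token within the sentence
    deprel: str
    char_span: tuple[int, int]  # offsets within the sentence text


@dataclass(frozen=True)
class AnnotatedSentence:
    """A sentence with token annotations and its character span in the note."""

    note: Note
    sentence_index: int
    char_span: tuple[int, int]  # offsets into note.text
    tokens: tuple[Token, ...]
    parsed: bool = False  # True when the backend provides real dependencies

    @property
    def text(self) -> str:
        return self.note.text[self.char_span[0] : self.char_span[1]]

    def token_text(self, span: tuple[int, int]) -> str:
        return " ".join(t.surface for t in self.tokens[span[0] : span[1]])


class Annotator(Protocol):
    """Backend contract: tokenize and annotate one sentence's text."""

    provides_dependencies: bool

    def annotate(self, text: str) -> tuple[Token, ...]: ...


# ---------------------------------------------------------------------------
# Sentence splitting

_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)|\n+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences: terminal punctuation or newlines end a
    sentence (short newline-terminated lines are common in nursing notes)."""
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _BOUNDARY.finditer(text):
        end = match.end() if not match.group().startswith("\n") else match.start()
        segment_text = text[start : end]
        if segment_text.strip():
            left = start + (len(segment_text) - len(segment_text.lstrip()))
            right = start + len(segment_text.rstrip())
            spans.append((left, right))
        start = match.end()
    tail = text[start:]
    if tail.strip():
        left = start + (len(tail) - len(tail.lstrip()))
        right = start + len(tail.rstrip())
        spans.append((left, right))
    return spans


# ---------------------------------------------------------------------------
# Rule-based annotation backend

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those"}
_PRONOUNS = {"he", "she", "it", "they", "we", "i", "you", "her", "him", "them",
             "us", "his", "its", "their", "herself", "himself", "who"}
_ADPOSITIONS = {"in", "on", "at", "of", "with", "for", "to", "from", "than",
                "by", "about", "during", "over", "under", "after", "before"}
_COORD_CONJ = {"and", "but", "or", "nor"}
_SUBORD_CONJ = {"if", "because", "while", "when", "although", "unless"}
_AUXILIARIES = {"is", "was", "were", "are", "be", "been", "being", "am",
                "do", "does", "did", "has", "have", "had",
                "will", "would", "can", "could", "shall", "should",
                "may", "might", "must"}
_COMMON_VERBS = {"reports", "report", "says", "say", "see", "sees", "feels",
                 "felt", "feel", "seems", "seem", "appears", "appear", "call",
                 "contact", "notify", "remains", "remain", "respond", "goes",
                 "went", "gets", "got", "keeps", "kept", "takes", "took",
                 "eats", "ate", "sleeps", "slept"}
_ADVERBS = {"today", "yesterday", "tomorrow", "now", "very", "still", "not",
            "never", "also", "again", "sharply", "steadily", "possibly",
            "probably", "well", "herself", "ago"}
_ADJECTIVES = {"angry", "anxious", "sad", "calm", "happy", "drowsy", "hungry",
               "good", "bad", "friendly", "nervous", "tired", "quiet",
               "restless", "stable", "alert", "strong", "clear"}

# Irregular comparative/superlative forms: word -> (lemma, degree).
_IRREGULAR_DEGREE = {
    "better": ("good", DEGREE_COMPARATIVE),
    "worse": ("bad", DEGREE_COMPARATIVE),
    "best": ("good", DEGREE_SUPERLATIVE),
    "worst": ("bad", DEGREE_SUPERLATIVE),
}

# -er/-est words that are not adjective comparatives (nouns, function words).
_SUFFIX_EXCLUSIONS = {
    "anger", "mother", "father", "sister", "brother", "daughter", "other",
    "another", "never", "under", "over", "after", "there", "here", "where",
    "whether", "rather", "together", "however", "either", "neither", "per",
    "her", "paper", "member", "remember", "water", "order", "number",
    "manner", "corner", "dinner", "summer", "winter", "letter", "matter",
    "answer", "offer", "transfer", "partner", "worker", "caregiver", "later",
    "chamber", "chapter", "center", "charter", "latest", "interest", "rest",
    "test", "best", "west", "arrest", "request", "suggest", "honest",
}

_IRREGULAR_LEMMAS = {
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "am": "be", "being": "be", "felt": "feel", "did": "do", "does": "do",
    "has": "have", "had": "have", "went": "go", "goes": "go", "got": "get",
    "gets": "get", "took": "take", "takes": "take", "ate": "eat",
    "slept": "sleep", "kept": "keep", "said": "say", "says": "say",
    "more": "much", "less": "little", "most": "much", "least": "little",
    "fewer": "few",
}


@dataclass(frozen=True)
class DegreeTable:
    """Language-configurable morphology for degree detection.

    ``comparative_suffixes``/``superlative_suffixes`` are tried in order;
    ``min_stem`` guards against short false stems ("anger" → "ang" is
    rejected); ``exclusions`` lists non-gradable words ending in a suffix.
    """

    comparative_suffixes: tuple[str, ...] = ("ier", "er")
    superlative_suffixes: tuple[str, ...] = ("iest", "est")
    irregular: dict = field(default_factory=lambda: dict(_IRREGULAR_DEGREE))
    exclusions: frozenset = frozenset(_SUFFIX_EXCLUSIONS)
    min_stem: int = 4

    def classify(self, word: str) -> tuple[str, str] | None:
        """Return (lemma, degree) for comparative/superlative forms, else None."""
        if word in self.irregular:
            return self.irregular[word]
        if word in self.exclusions:
            return None
        for suffixes, degree in (
            (self.superlative_suffixes, DEGREE_SUPERLATIVE),
            (self.comparative_suffixes, DEGREE_COMPARATIVE),
        ):
            for suffix in suffixes:
                if word.endswith(suffix):
                    stem = word[: -len(suffix)]
                    if len(stem) < self.min_stem:
                        continue
                    if suffix.startswith("i"):
                        lemma = stem + "y"  # angrier -> angry
                    elif len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiou":
                        lemma = stem[:-1]  # sadder -> sad
                    else:
                        lemma = stem  # stronger -> strong
                    return lemma, degree
        return None


class RuleBasedAnnotator:
    """Deterministic table/suffix annotator satisfying the Token contract.

    Emits a flat dependency tree (every token attached to a single root, the
    first finite verb if any) and therefore declares
    ``provides_dependencies = False``.
    """

    provides_dependencies = False

    def __init__(self, degree_table: DegreeTable | None = None) -> None:
        self.degree_table = degree_table or DegreeTable()

    def _lemma(self, word: str) -> str:
        if word in _IRREGULAR_LEMMAS:
            return _IRREGULAR_LEMMAS[word]
        if word.endswith("ies") and len(word) > 4:
            return word[:-3] + "y"
        if word.endswith("sses") or word.endswith("ches") or word.endswith("shes"):
            return word[:-2]
        if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
            return word[:-1]
        return word

    def _tag(self, word: str) -> tuple[str, str, str]:
        """Return (lemma, pos, degree) for one lowercase word token."""
        degree_hit = self.degree_table.classify(word)
        if degree_hit is not None:
            return degree_hit[0], "ADJ", degree_hit[1]
        if word in _AUXILIARIES:
            return _IRREGULAR_LEMMAS.get(word, word), "AUX", DEGREE_NA
        if word in _COMMON_VERBS or (
            word not in _ADVERBS
            and word not in _ADJECTIVES
            and (word.endswith("ed") or word.endswith("ing"))
            and len(word) > 4
        ):
            return self._lemma(word), "VERB", DEGREE_NA
        if word in _DETERMINERS:
            return word, "DET", DEGREE_NA
        if word in _PRONOUNS:
            return word, "PRON", DEGREE_NA
        if word in _ADPOSITIONS:
            return word, "ADP", DEGREE_NA
        if word in _COORD_CONJ:
            return word, "CCONJ", DEGREE_NA
        if word in _SUBORD_CONJ:
            return word, "SCONJ", DEGREE_NA
        if word in _ADVERBS:
            return word, "ADV", DEGREE_POSITIVE
        if word in _ADJECTIVES:
            return word, "ADJ", DEGREE_POSITIVE
        return self._lemma(word), "NOUN", DEGREE_NA

    def annotate(self, text: str) -> tuple[Token, ...]:
        raw = [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
        tokens: list[Token] = []
        for surface, start, end in raw:
            if not surface[0].isalnum():
                lemma, pos, degree = surface, "PUNCT", DEGREE_NA
            else:
                lemma, pos, degree = self._tag(surface.casefold())
            tokens.append(
                Token(surface=surface, lemma=lemma, pos=pos, degree=degree,
                      head=0, deprel="dep", char_span=(start, end))
            )
        if not tokens:
            return ()
        root = next((i for i, t in enumerate(tokens) if t.pos in ("VERB", "AUX")), 0)
        annotated = []
        for i, t in enumerate(tokens):
            if i == root:
                annotated.append(replace(t, head=i, deprel="root"))
            else:
                annotated.append(replace(t, head=root, deprel="dep"))
        return tuple(annotated)


_DEFAULT_ANNOTATOR = RuleBasedAnnotator()


def segment(note: Note, annotator: Annotator | None = None) -> list[AnnotatedSentence]:
    """Split a note into annotated sentences (step 1 of the pipeline).

    Deterministic and a pure function of the note text; identifiers and
    dates never influence the splitting.
    """
    annotator = annotator or _DEFAULT_ANNOTATOR
    sentences: list[AnnotatedSentence] = []
    for index, (start, end) in enumerate(split_sentences(note.text)):
        try:
            tokens = annotator.annotate(note.text[start:end])
        except Exception as exc:  # pragma: no cover - backend failure path
            raise PreprocessError(
                f"annotation backend failed on note {note.note_id!r}: {exc}"
            ) from exc
        sentences.append(
            AnnotatedSentence(
                note=note,
                sentence_index=index,
                char_span=(start, end),
                tokens=tokens,
                parsed=annotator.provides_dependencies,
            )
        )
    return sentences


def annotate_degree(
    sentence: AnnotatedSentence, degree_table: DegreeTable | None = None
) -> AnnotatedSentence:
    """Ensure every adjective/adverb token carries a degree; idempotent."""
    table = degree_table or DegreeTable()
    new_tokens = []
    for token in sentence.tokens:
        if token.pos not in ("ADJ", "ADV"):
            new_tokens.append(replace(token, degree=DEGREE_NA))
            continue
        hit = table.classify(token.surface.casefold())
        if hit is not None:
            new_tokens.append(replace(token, degree=hit[1]))
        elif token.degree == DEGREE_NA:
            new_tokens.append(replace(token, degree=DEGREE_POSITIVE))
        else:
            new_tokens.append(token)
    return replace(sentence, tokens=tuple(new_tokens))


def sentence_from_text(
    text: str,
    annotator: Annotator | None = None,
    note: Note | None = None,
) -> AnnotatedSentence:
    """Annotate an isolated sentence (used by evaluation on labelled sets)."""
    if note is None:
        note = Note(patient_id="_", trajectory_id="_", note_id="_",
                    date=_date(2000, 1, 1), text=text)
    sentences = segment(note, annotator)
    if len(sentences) == 1:
        return sentences[0]
    # Multi-sentence text: treat the whole string as one unit.
    annotator = annotator or _DEFAULT_ANNOTATOR
    return AnnotatedSentence(
        note=note, sentence_index=0, char_span=(0, len(text)),
        tokens=annotator.annotate(text), parsed=annotator.provides_dependencies,
    )
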