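"""Theme filter, change filter and candidate pairing (pipeline steps 2–3).

A sentence passes the theme filter when at least one theme phrase matches,
and the change filter when it contains a change cue: either a lexicon
change phrase ("improvement", "more") or a comparative adjective form
("angrier", detected via morphological degree).  Sentences failing either
filter are cancelled.  Surviving theme matches are paired with their
nearest change cue to form scoring candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lexicon import Lexicon, LexiconEntry, lookup
from .preprocess import DEGREE_COMPARATIVE, AnnotatedSentence

__all__ = ["Match", "CandidatePair", "theme_filter", "change_filter", "pair_candidates"]

SOURCE_LEXICON = "lexicon"
SOURCE_COMPARATIVE = "comparative"


@dataclass(frozen=True)
class Match:
    """A theme or change hit inside one sentence.

    ``value`` is the theme polarity for theme matches and the change
    direction for change matches.  Comparative-form matches always carry
    direction +1 — "angrier" means more anger; the theme phrase's polarity
    supplies the sign of the pair.
    """

    span: tuple[int, int]  # half-open token indices
    source: str  # "lexicon" | "comparative"
    value: int  # −1 or +1
    entry: LexiconEntry | None = None
    surface: str = ""

    def __post_init__(self) -> None:
        if self.source == SOURCE_COMPARATIVE and self.value != 1:
            raise ValueError("comparative matches always carry direction +1")

    def distance_to(self, other: "Match") -> int:
        """Token gap between two non-overlapping spans (0 = adjacent)."""
        if self.span[0] >= other.span[1]:
            return self.span[0] - other.span[1]
        if other.span[0] >= self.span[1]:
            return other.span[0] - self.span[1]
        return 0

    def overlaps(self, other: "Match") -> bool:
        return self.span[0] < other.span[1] and other.span[0] < self.span[1]


@dataclass(frozen=True)
class CandidatePair:
    """A (theme match, change match) pair from one sentence, pre context filter."""

    theme: str
    theme_match: Match
    change_match: Match

    def __post_init__(self) -> None:
        if self.theme_match.source != SOURCE_LEXICON:
            raise ValueError("theme matches must come from the lexicon")


def theme_filter(
    sentence: AnnotatedSentence, lexicon: Lexicon
) -> dict[str, list[Match]]:
    """Step 2: per-theme phrase matches; an empty map means the sentence is
    rejected at this stage."""
    by_theme: dict[str, list[Match]] = {}
    for span, entry in lookup(lexicon, sentence.tokens, lexicon.theme_entries()):
        match = Match(
            span=span,
            source=SOURCE_LEXICON,
            value=entry.polarity,
            entry=entry,
            surface=sentence.token_text(span),
        )
        by_theme.setdefault(entry.theme, []).append(match)
    for matches in by_theme.values():
        matches.sort(key=lambda m: m.span)
    return by_theme


def change_filter(sentence: AnnotatedSentence, lexicon: Lexicon) -> list[Match]:
    """Step 3: change cues — lexicon change phrases plus comparative forms.

    An empty result cancels the sentence.  A token already covered by a
    lexicon change match does not additionally contribute a comparative
    pseudo-match.
    """
    matches: list[Match] = []
    for span, entry in lookup(lexicon, sentence.tokens, lexicon.change_entries()):
        matches.append(
            Match(span=span, source=SOURCE_LEXICON, value=entry.polarity,
                  entry=entry, surface=sentence.token_text(span))
        )
    covered = {i for m in matches for i in range(*m.span)}
    for i, token in enumerate(sentence.tokens):
        if token.degree == DEGREE_COMPARATIVE and i not in covered:
            matches.append(
                Match(span=(i, i + 1), source=SOURCE_COMPARATIVE, value=1,
                      surface=token.surface)
            )
    matches.sort(key=lambda m: m.span)
    return matches


def pair_candidates(
    theme_matches: dict[str, list[Match]], change_matches: list[Match]
) -> list[CandidatePair]:
    """Pair each theme match with its nearest change cue (ties → leftmost).

    One change cue may serve several theme matches — "more anxious and sad"
    yields two pairs sharing "more".  A token span cannot act as both theme
    and change of the same pair.
    """
    pairs: list[CandidatePair] = []
    for theme in sorted(theme_matches):
        for theme_match in theme_matches[theme]:
            candidates = [c for c in change_matches if not c.overlaps(theme_match)]
            if not candidates:
                continue
            best = min(candidates, key=lambda c: (theme_match.distance_to(c), c.span))
            pairs.append(
                CandidatePair(theme=theme, theme_match=theme_match, change_match=best)
            )
    return pairs
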