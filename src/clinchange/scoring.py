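"""Sentence sentiment scoring and patient/trajectory aggregation (step 5).

Each accepted (theme phrase, change phrase) pair contributes the product of
the theme polarity and the change direction; per-sentence theme scores are
the sum of the pair products ("more anxiety" → −1, "participation
improved" → +1, "The patient was more anxious and sad" → −2).  Summary
scores are exact rational means over the sentences that passed all
filters; a group with no passing sentence has an undefined mean, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .context import ContextRuleSet, ContextVerdict, LinkageConfig, apply_context_filter
from .filters import change_filter, pair_candidates, theme_filter
from .lexicon import Lexicon
from .preprocess import Annotator, Note, segment

__all__ = [
    "SentenceScore",
    "ThemeSummary",
    "SentenceTrace",
    "StageCounts",
    "PipelineResult",
    "score_sentence",
    "aggregate",
    "run_pipeline",
]

STAGE_NO_THEME = "step2"
STAGE_NO_CHANGE = "step3"
STAGE_CONTEXT = "step4"
STAGE_SCORED = "scored"


@dataclass(frozen=True)
class SentenceScore:
    """Integer sentiment of one sentence for one theme."""

    note_id: str
    sentence_index: int
    theme: str
    score: int
    contributing_pairs: tuple[tuple[int, int], ...]  # (polarity, direction)
    patient_id: str = "_"
    trajectory_id: str = "_"

    def __post_init__(self) -> None:
        if self.score != sum(p * d for p, d in self.contributing_pairs):
            raise ValueError("score must equal the sum of pair products")
        for polarity, direction in self.contributing_pairs:
            if polarity not in (-1, 1) or direction not in (-1, 1):
                raise ValueError("pair polarity and direction must be ±1")


@dataclass(frozen=True)
class ThemeSummary:
    """Per-group theme summary: counts and mean sentiment.

    ``mean_sentiment`` is an exact rational, or None (undefined) when no
    sentence passed all filters for the group.
    """

    key_id: str
    key_kind: str  # "patient" | "trajectory"
    theme: str
    n_theme_sentences: int
    n_change_sentences: int
    mean_sentiment: Fraction | None

    def __post_init__(self) -> None:
        if self.n_change_sentences > self.n_theme_sentences:
            raise ValueError("change sentences cannot exceed theme sentences")
        if (self.mean_sentiment is None) != (self.n_change_sentences == 0):
            raise ValueError("mean is undefined exactly when no sentence passed")


@dataclass(frozen=True)
class SentenceTrace:
    """Where one sentence stopped in the pipeline, for one theme."""

    note_id: str
    sentence_index: int
    theme: str
    stage: str  # step2 | step3 | step4 | scored
    failed_checks: tuple[str, ...] = ()


@dataclass
class StageCounts:
    """Per-theme sentence counts through the pipeline stages."""

    n_sentences: int = 0
    n_theme_pass: int = 0
    n_change_pass: int = 0
    n_accepted: int = 0


@dataclass
class PipelineResult:
    scores: list[SentenceScore]
    summaries: list[ThemeSummary]
    stage_counts: dict[str, StageCounts] = field(default_factory=dict)
    sentence_traces: list[SentenceTrace] = field(default_factory=list)


def score_sentence(verdicts: Sequence[ContextVerdict], **refs) -> list[SentenceScore]:
    """One SentenceScore per theme with at least one accepted pair."""
    by_theme: dict[str, list[tuple[int, int]]] = {}
    for verdict in verdicts:
        if not verdict.accepted:
            continue
        pair = verdict.pair
        by_theme.setdefault(pair.theme, []).append(
            (pair.theme_match.value, pair.change_match.value)
        )
    refs.setdefault("note_id", "_")
    refs.setdefault("sentence_index", 0)
    return [
        SentenceScore(
            theme=theme,
            score=sum(p * d for p, d in pairs),
            contributing_pairs=tuple(pairs),
            **refs,
        )
        for theme, pairs in sorted(by_theme.items())
    ]


def aggregate(
    scores: Iterable[SentenceScore],
    key: str,
    theme: str,
    n_theme_sentences: int | None = None,
    key_id: str | None = None,
) -> ThemeSummary:
    """Mean sentiment over the sentences that passed all filters for one group.

    ``scores`` must share one grouping key and one theme.  The example from
    the field: sentence scores {−2, 1, 2} give a mean of 1/3.
    """
    if key not in ("patient", "trajectory"):
        raise ValueError(f"key must be 'patient' or 'trajectory', got {key!r}")
    attr = "patient_id" if key == "patient" else "trajectory_id"
    scores = list(scores)
    key_ids = {getattr(s, attr) for s in scores}
    themes = {s.theme for s in scores}
    if len(key_ids) > 1:
        raise ValueError(f"mixed grouping keys in aggregate: {sorted(key_ids)}")
    if themes - {theme}:
        raise ValueError(f"scores carry themes other than {theme!r}: {sorted(themes)}")
    n_change = len(scores)
    mean = Fraction(sum(s.score for s in scores), n_change) if n_change else None
    n_theme = n_theme_sentences if n_theme_sentences is not None else n_change
    if key_ids and key_id is not None and key_ids != {key_id}:
        raise ValueError(f"scores belong to {sorted(key_ids)}, not {key_id!r}")
    return ThemeSummary(
        key_id=next(iter(key_ids)) if key_ids else (key_id or "_"),
        key_kind=key,
        theme=theme,
        n_theme_sentences=n_theme,
        n_change_sentences=n_change,
        mean_sentiment=mean,
    )


def _summarize(
    scores: list[SentenceScore],
    theme_sentence_keys: dict[str, dict[str, set[tuple[str, int]]]],
    themes: Sequence[str],
    key: str,
) -> list[ThemeSummary]:
    attr = "patient_id" if key == "patient" else "trajectory_id"
    summaries = []
    group_ids = sorted(
        {getattr(s, attr) for s in scores}
        | {g for theme_map in theme_sentence_keys.values() for g in theme_map}
    )
    for group_id in group_ids:
        for theme in themes:
            group_scores = [
                s for s in scores if getattr(s, attr) == group_id and s.theme == theme
            ]
            n_theme = len(theme_sentence_keys.get(theme, {}).get(group_id, set()))
            if n_theme == 0 and not group_scores:
                continue
            summaries.append(
                aggregate(group_scores, key, theme,
                          n_theme_sentences=n_theme, key_id=group_id)
            )
    return summaries


def run_pipeline(
    notes: Sequence[Note],
    lexicon: Lexicon,
    rules: ContextRuleSet | None = None,
    annotator: Annotator | None = None,
    linkage: LinkageConfig | None = None,
    group_by: Sequence[str] = ("trajectory", "patient"),
) -> PipelineResult:
    """Run all five pipeline stages over a collection of notes.

    Deterministic for fixed inputs.  Summaries are emitted for every
    grouping key in ``group_by`` (trajectory first by default, matching
    the admission-episode reporting unit).  The trace records, per theme,
    how many sentences were segmented, passed the theme filter, passed the
    change filter, and had at least one accepted pair.
    """
    rules = rules or ContextRuleSet.empty()
    themes = lexicon.themes
    stage_counts = {theme: StageCounts() for theme in themes}
    scores: list[SentenceScore] = []
    traces: list[SentenceTrace] = []
    # per theme -> group id -> set of (note_id, sentence_index) with a theme phrase
    theme_keys: dict[str, dict[str, dict[str, set]]] = {
        g: {theme: {} for theme in themes} for g in group_by
    }

    for note in notes:
        for sentence in segment(note, annotator):
            theme_matches = theme_filter(sentence, lexicon)
            change_matches = change_filter(sentence, lexicon)
            pairs = pair_candidates(theme_matches, change_matches)
            verdicts = apply_context_filter(sentence, pairs, rules, linkage)
            sentence_scores = score_sentence(
                verdicts,
                note_id=note.note_id,
                sentence_index=sentence.sentence_index,
                patient_id=note.patient_id,
                trajectory_id=note.trajectory_id,
            )
            scores.extend(sentence_scores)
            scored_themes = {s.theme for s in sentence_scores}
            for theme in themes:
                counts = stage_counts[theme]
                counts.n_sentences += 1
                if theme not in theme_matches:
                    traces.append(SentenceTrace(note.note_id, sentence.sentence_index,
                                                theme, STAGE_NO_THEME))
                    continue
                counts.n_theme_pass += 1
                for key in group_by:
                    gid = note.patient_id if key == "patient" else note.trajectory_id
                    theme_keys[key][theme].setdefault(gid, set()).add(
                        (note.note_id, sentence.sentence_index)
                    )
                if not change_matches:
                    traces.append(SentenceTrace(note.note_id, sentence.sentence_index,
                                                theme, STAGE_NO_CHANGE))
                    continue
                counts.n_change_pass += 1
                if theme in scored_themes:
                    counts.n_accepted += 1
                    traces.append(SentenceTrace(note.note_id, sentence.sentence_index,
                                                theme, STAGE_SCORED))
                else:
                    failed = tuple(sorted({
                        name
                        for verdict in verdicts
                        if verdict.pair.theme == theme
                        for name, result in verdict.checks.items()
                        if result == "fail"
                    }))
                    traces.append(SentenceTrace(note.note_id, sentence.sentence_index,
                                                theme, STAGE_CONTEXT, failed))

    summaries: list[ThemeSummary] = []
    for key in group_by:
        summaries.extend(_summarize(scores, theme_keys[key], themes, key))
    return PipelineResult(
        scores=scores,
        summaries=summaries,
        stage_counts=stage_counts,
        sentence_traces=traces,
    )
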