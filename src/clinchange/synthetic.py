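"""Synthetic annotated clinical-note corpora with constructive ground truth.

Generates notes whose sentences mix theme phrases, change cues
(lexicon words and comparative forms), context corruptions (negation,
hypothetical framing, non-patient experiencers, history references),
repetition and distractor text — with per-sentence, per-theme
accept/reject labels and expected sentiment scores computed at generation
time from the templates, never by running the pipeline.  This keeps the
ground truth independent of the system it validates.

Every template is built from phrases guaranteed to be covered by the
fixture lexicon and rule files, so on a matched configuration the pipeline
should recover the labels exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields as dataclass_fields
from datetime import date, timedelta
from fractions import Fraction
from importlib import resources
from pathlib import Path

from .context import ContextRuleSet, load_context_rules
from .evaluation import LabeledSentence
from .lexicon import Lexicon, LexiconEntry, load_lexicon
from .preprocess import Note
from .scoring import (
    STAGE_CONTEXT,
    STAGE_NO_CHANGE,
    STAGE_NO_THEME,
    STAGE_SCORED,
    ThemeSummary,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruthRecord",
    "GroundTruth",
    "fixture_lexicon",
    "fixture_rules",
    "generate",
    "expected_summaries",
]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("clinchange").joinpath("data", name)))


def fixture_lexicon() -> Lexicon:
    """The packaged English fixture lexicon (four themes + change phrases)."""
    return load_lexicon(_data_path("lexicon_en.tsv"))


def fixture_rules(language: str = "en") -> ContextRuleSet:
    """The packaged starter context-rule set ('en' or 'nl')."""
    return load_context_rules(_data_path(f"context_rules_{language}.tsv"))


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus shape and injection rates.

    Defaults echo the sparsity seen in inpatient psychiatric notes, where
    sentences mentioning a theme are common but sentences describing a
    genuine, valid change in it are rare (roughly one in twelve theme
    sentences).
    """

    n_patients: int = 20
    notes_per_patient: tuple[int, int] = (5, 15)
    sentences_per_note: tuple[int, int] = (3, 10)
    p_theme: float = 0.08  # per theme, per sentence
    p_change_given_theme: float = 0.10
    p_negation: float = 0.05
    p_hypothetical: float = 0.05
    p_nonpatient: float = 0.05
    p_history: float = 0.05
    polarity_mix: float = 0.5  # share of positive-polarity theme phrase picks
    p_repeat: float = 0.15  # chance a note opens with the patient's stock status line
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            if f.name.startswith("p_") or f.name == "polarity_mix":
                value = getattr(self, f.name)
                if not 0.0 <= value <= 1.0:
                    raise GeneratorConfigError(f"{f.name} must be in [0, 1], got {value}")
        if self.n_patients < 1:
            raise GeneratorConfigError("n_patients must be >= 1")
        for name in ("notes_per_patient", "sentences_per_note"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise GeneratorConfigError(f"{name} must be a range with 1 <= lo <= hi")
        if self.corruption_total > 1.0:
            raise GeneratorConfigError(
                "corruption probabilities sum to more than 1; no template mix "
                "can satisfy that demand"
            )

    @property
    def corruption_total(self) -> float:
        return self.p_negation + self.p_hypothetical + self.p_nonpatient + self.p_history


@dataclass(frozen=True)
class GroundTruthRecord:
    """Constructive truth for one (sentence, theme)."""

    patient_id: str
    trajectory_id: str
    note_id: str
    sentence_index: int
    sentence_text: str
    theme: str
    has_theme: bool
    label: str  # accept | reject
    expected_score: int | None  # set exactly when label == accept
    corruption: str | None  # negation | hypothetical | nonpatient | history | no_change
    expected_stage: str  # step2 | step3 | step4 | scored

    def __post_init__(self) -> None:
        if (self.expected_score is not None) != (self.label == "accept"):
            raise ValueError("expected_score is set exactly for accepted records")


@dataclass
class GroundTruth:
    records: list[GroundTruthRecord] = field(default_factory=list)

    def labels(self, themes_with_phrase_only: bool = False) -> list[LabeledSentence]:
        """Flatten to accept/reject sentence labels, one per (sentence, theme)."""
        return [
            LabeledSentence(text=r.sentence_text, theme=r.theme, label=r.label)
            for r in self.records
            if r.has_theme or not themes_with_phrase_only
        ]

    def stage_histogram(self, theme: str) -> dict[str, int]:
        histogram = {STAGE_NO_THEME: 0, STAGE_NO_CHANGE: 0, STAGE_CONTEXT: 0,
                     STAGE_SCORED: 0}
        for record in self.records:
            if record.theme == theme:
                histogram[record.expected_stage] += 1
        return histogram


# ---------------------------------------------------------------------------
# Templates.  Clause tuples: (text, direction or None, corruption or None).
# Own change cues are positioned so the nearest-change pairing rule always
# resolves to the clause's own cue (comparative clauses are fronted during
# sentence assembly to preserve this across clause boundaries).

_DISTRACTORS = (
    "Routine checks completed today",
    "Medication administered as prescribed",
    "Attended the morning meeting",
    "Slept through the night",
    "Plan reviewed with the team",
    "Vital signs recorded",
)

_COMPARATIVES = ("stronger", "clearer")  # generic comparatives, direction +1


def _clean_clause(rng: random.Random, phrase: str) -> tuple[str, int, bool]:
    """Return (clause text, direction, fronted) for a valid change statement."""
    template = rng.randrange(5)
    if template == 0:
        return f"{phrase} increased", 1, False
    if template == 1:
        return f"more {phrase} than yesterday", 1, False
    if template == 2:
        return f"less {phrase} than before", -1, False
    if template == 3:
        comparative = rng.choice(_COMPARATIVES)
        return f"{phrase} seemed {comparative} today", 1, True
    return f"improvement in {phrase}", 1, False


_CORRUPTION_CLAUSES = {
    "negation": "no increase in {phrase}",
    "hypothetical": "if {phrase} increases , contact staff",
    "nonpatient": "mother reports more {phrase}",
    "history": "years ago {phrase} increased sharply",
}

_NO_CHANGE_CLAUSE = "{phrase} was discussed with the patient"

_REQUIRED_CHANGE_PHRASES = ("increased", "more", "less", "improvement", "increase",
                            "increases")
_REQUIRED_TRIGGERS = {
    "negation": "no",
    "hypothetical": "if",
    "non-patient-experiencer": "mother",
    "non-current": "years ago",
}


def _check_coverage(lexicon: Lexicon, rules: ContextRuleSet) -> None:
    change_phrases = {e.phrase for e in lexicon.change_entries()}
    missing = [p for p in _REQUIRED_CHANGE_PHRASES if p not in change_phrases]
    if missing:
        raise GeneratorConfigError(f"lexicon lacks template change phrases: {missing}")
    for kind, trigger in _REQUIRED_TRIGGERS.items():
        if all(r.trigger != trigger for r in rules.of_kind(kind)):
            raise GeneratorConfigError(
                f"rule set lacks the {kind!r} trigger {trigger!r} used by templates"
            )
    if ";" not in rules.terminators:
        raise GeneratorConfigError("rule set must terminate scopes at ';'")
    for theme in lexicon.themes:
        if not lexicon.theme_entries(theme):
            raise GeneratorConfigError(f"theme {theme!r} has no lexicon entries")


def _pick_entry(rng: random.Random, lexicon: Lexicon, theme: str,
                polarity_mix: float) -> LexiconEntry:
    entries = lexicon.theme_entries(theme)
    positives = [e for e in entries if e.polarity == 1]
    negatives = [e for e in entries if e.polarity == -1]
    pool = positives if (positives and rng.random() < polarity_mix) else negatives
    if not pool:
        pool = list(entries)
    return rng.choice(list(pool))


def generate(
    config: GeneratorConfig,
    lexicon: Lexicon | None = None,
    rules: ContextRuleSet | None = None,
) -> tuple[list[Note], GroundTruth]:
    """Build a corpus and its constructive ground truth.

    Deterministic: a fixed config (including seed) always yields a
    byte-identical corpus.
    """
    lexicon = lexicon or fixture_lexicon()
    rules = rules or fixture_rules()
    _check_coverage(lexicon, rules)
    rng = random.Random(config.seed)
    themes = list(lexicon.themes)
    notes: list[Note] = []
    truth = GroundTruth()

    for patient_number in range(config.n_patients):
        patient_id = f"p{patient_number:03d}"
        stock_line = rng.choice(_DISTRACTORS)
        n_notes = rng.randint(*config.notes_per_patient)
        n_trajectories = 1 if n_notes < 4 else rng.choice((1, 2))
        split_at = n_notes if n_trajectories == 1 else rng.randint(2, n_notes - 2)
        for note_number in range(n_notes):
            trajectory = 1 if note_number < split_at else 2
            trajectory_id = f"{patient_id}-T{trajectory}"
            note_id = f"{patient_id}-n{note_number:03d}"
            note_date = date(2020, 1, 1) + timedelta(days=note_number)
            sentences: list[str] = []
            sentence_meta: list[dict] = []  # per sentence: theme -> clause info

            n_sentences = rng.randint(*config.sentences_per_note)
            repeat_first = rng.random() < config.p_repeat
            for sentence_number in range(n_sentences):
                if repeat_first and sentence_number == 0:
                    sentences.append(stock_line + " .")
                    sentence_meta.append({})
                    continue
                clauses: list[tuple[str, dict, bool]] = []
                for theme in themes:
                    if rng.random() >= config.p_theme:
                        continue
                    entry = _pick_entry(rng, lexicon, theme, config.polarity_mix)
                    if rng.random() >= config.p_change_given_theme:
                        clauses.append((
                            _NO_CHANGE_CLAUSE.format(phrase=entry.phrase),
                            {"theme": theme, "label": "reject",
                             "corruption": "no_change", "score": None,
                             "has_change_cue": False},
                            False,
                        ))
                        continue
                    u = rng.random()
                    cumulative = 0.0
                    corruption = None
                    for kind in ("negation", "hypothetical", "nonpatient", "history"):
                        cumulative += getattr(config, f"p_{kind}")
                        if u < cumulative:
                            corruption = kind
                            break
                    if corruption is not None:
                        clauses.append((
                            _CORRUPTION_CLAUSES[corruption].format(phrase=entry.phrase),
                            {"theme": theme, "label": "reject",
                             "corruption": corruption, "score": None,
                             "has_change_cue": True},
                            False,
                        ))
                    else:
                        text, direction, fronted = _clean_clause(rng, entry.phrase)
                        clauses.append((
                            text,
                            {"theme": theme, "label": "accept", "corruption": None,
                             "score": entry.polarity * direction,
                             "has_change_cue": True},
                            fronted,
                        ))
                if not clauses:
                    sentences.append(rng.choice(_DISTRACTORS) + " .")
                    sentence_meta.append({})
                    continue
                # Comparative clauses go first so every theme's nearest change
                # cue stays within its own clause.
                clauses.sort(key=lambda c: 0 if c[2] else 1)
                sentences.append(" ; ".join(c[0] for c in clauses) + " .")
                sentence_meta.append({c[1]["theme"]: c[1] for c in clauses})

            text = " ".join(sentences)
            notes.append(Note(patient_id=patient_id, trajectory_id=trajectory_id,
                              note_id=note_id, date=note_date, text=text))
            for sentence_index, meta in enumerate(sentence_meta):
                sentence_text = sentences[sentence_index].rstrip(" .")
                any_change_cue = any(m["has_change_cue"] for m in meta.values())
                for theme in themes:
                    info = meta.get(theme)
                    if info is None:
                        record = GroundTruthRecord(
                            patient_id, trajectory_id, note_id, sentence_index,
                            sentence_text, theme, has_theme=False, label="reject",
                            expected_score=None, corruption=None,
                            expected_stage=STAGE_NO_THEME,
                        )
                    elif info["label"] == "accept":
                        record = GroundTruthRecord(
                            patient_id, trajectory_id, note_id, sentence_index,
                            sentence_text, theme, has_theme=True, label="accept",
                            expected_score=info["score"], corruption=None,
                            expected_stage=STAGE_SCORED,
                        )
                    else:
                        if info["corruption"] == "no_change":
                            stage = STAGE_CONTEXT if any_change_cue else STAGE_NO_CHANGE
                        else:
                            stage = STAGE_CONTEXT
                        record = GroundTruthRecord(
                            patient_id, trajectory_id, note_id, sentence_index,
                            sentence_text, theme, has_theme=True, label="reject",
                            expected_score=None, corruption=info["corruption"],
                            expected_stage=stage,
                        )
                    truth.records.append(record)
    return notes, truth


def expected_summaries(truth: GroundTruth, key: str = "trajectory") -> list[ThemeSummary]:
    """Analytic aggregation oracle computed directly from the ground truth."""
    if key not in ("patient", "trajectory"):
        raise ValueError(f"key must be 'patient' or 'trajectory', got {key!r}")
    attr = "patient_id" if key == "patient" else "trajectory_id"
    groups: dict[tuple[str, str], dict] = {}
    for record in truth.records:
        cell = groups.setdefault(
            (getattr(record, attr), record.theme),
            {"n_theme": 0, "scores": []},
        )
        if record.has_theme:
            cell["n_theme"] += 1
        if record.label == "accept":
            cell["scores"].append(record.expected_score)
    summaries = []
    for (group_id, theme), cell in sorted(groups.items()):
        if cell["n_theme"] == 0 and not cell["scores"]:
            continue
        n_change = len(cell["scores"])
        summaries.append(
            ThemeSummary(
                key_id=group_id,
                key_kind=key,
                theme=theme,
                n_theme_sentences=cell["n_theme"],
                n_change_sentences=n_change,
                mean_sentiment=(
                    Fraction(sum(cell["scores"]), n_change) if n_change else None
                ),
            )
        )
    return summaries
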