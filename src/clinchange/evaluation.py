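"""Validation against human accept/reject sentence annotations.

A sentence is predicted "accept" for a theme exactly when it passes all
pipeline filters for that theme (i.e. it receives a sentence score).
Predictions are compared with human span-level labels per theme, yielding
confusion counts and accuracy/precision/recall/F1.  Ratios with a zero
denominator are reported as missing (None), never as 0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .context import ContextRuleSet, LinkageConfig
from .lexicon import Lexicon
from .preprocess import Annotator, Note, sentence_from_text
from .scoring import run_pipeline

__all__ = [
    "LabeledSentence",
    "EvalReport",
    "predict_label",
    "evaluate",
    "evaluate_predictions",
    "harmonic_f1",
    "load_labeled_sentences",
    "write_report_csv",
]

ACCEPT = "accept"
REJECT = "reject"


@dataclass(frozen=True)
class LabeledSentence:
    """One human-annotated sentence for one theme."""

    text: str
    theme: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (ACCEPT, REJECT):
            raise ValueError(f"label must be 'accept' or 'reject', got {self.label!r}")


def harmonic_f1(precision: float, recall: float) -> float | None:
    """F1 as the harmonic mean of precision and recall; None when degenerate."""
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and derived metrics for one theme."""

    theme: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.n if self.n else None

    @property
    def precision(self) -> float | None:
        denominator = self.tp + self.fp
        return self.tp / denominator if denominator else None

    @property
    def recall(self) -> float | None:
        denominator = self.tp + self.fn
        return self.tp / denominator if denominator else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        return harmonic_f1(p, r)


def predict_label(
    text: str,
    theme: str,
    lexicon: Lexicon,
    rules: ContextRuleSet | None = None,
    annotator: Annotator | None = None,
    linkage: LinkageConfig | None = None,
) -> str:
    """Pipeline label for an isolated sentence: accept iff it is scored for
    the theme after all filters."""
    sentence = sentence_from_text(text, annotator)
    result = run_pipeline([sentence.note], lexicon, rules, annotator, linkage,
                          group_by=())
    return ACCEPT if any(s.theme == theme for s in result.scores) else REJECT


def evaluate_predictions(
    labels: Sequence[LabeledSentence], predictions: Sequence[str]
) -> dict[str, EvalReport]:
    """Confusion counts per theme from parallel gold labels and predictions."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions must be parallel sequences")
    counts: dict[str, dict[str, int]] = {}
    for labeled, predicted in zip(labels, predictions):
        cell = counts.setdefault(labeled.theme, {"tp": 0, "fp": 0, "fn": 0, "tn": 0})
        if predicted == ACCEPT and labeled.label == ACCEPT:
            cell["tp"] += 1
        elif predicted == ACCEPT:
            cell["fp"] += 1
        elif labeled.label == ACCEPT:
            cell["fn"] += 1
        else:
            cell["tn"] += 1
    return {
        theme: EvalReport(theme=theme, **cell) for theme, cell in sorted(counts.items())
    }


def evaluate(
    labels: Sequence[LabeledSentence],
    lexicon: Lexicon,
    rules: ContextRuleSet | None = None,
    annotator: Annotator | None = None,
    linkage: LinkageConfig | None = None,
) -> dict[str, EvalReport]:
    """Run the pipeline over every labelled sentence and score it against
    the human labels, one report per theme."""
    known = set(lexicon.themes)
    unknown = {l.theme for l in labels} - known
    if unknown:
        raise ValueError(f"labels reference unknown themes: {sorted(unknown)}")
    predictions = [
        predict_label(l.text, l.theme, lexicon, rules, annotator, linkage)
        for l in labels
    ]
    return evaluate_predictions(labels, predictions)


def load_labeled_sentences(path: str | Path) -> list[LabeledSentence]:
    """Read labels from annotation JSONL (text/label/answer) or CSV
    (text/theme/label)."""
    path = Path(path)
    labels: list[LabeledSentence] = []
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with path.open(encoding="utf-8") as fh:
            for line_number, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                record = json.loads(line)
                try:
                    labels.append(
                        LabeledSentence(
                            text=record["text"],
                            theme=record["label"],
                            label=record["answer"],
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise ValueError(f"{path} line {line_number}: {exc}") from exc
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for row_number, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    labels.append(
                        LabeledSentence(
                            text=row["text"], theme=row["theme"], label=row["label"]
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise ValueError(f"{path} row {row_number}: {exc}") from exc
    return labels


def write_report_csv(reports: Mapping[str, EvalReport], path: str | Path) -> None:
    """One row per theme with counts and metrics; missing ratios as empty cells."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["theme", "tp", "fp", "fn", "tn", "accuracy", "precision", "recall", "f1"]
        )
        for theme in sorted(reports):
            r = reports[theme]
            def fmt(x: float | None) -> str:
                return "" if x is None else f"{x:.3f}"
            writer.writerow(
                [theme, r.tp, r.fp, r.fn, r.tn,
                 fmt(r.accuracy), fmt(r.precision), fmt(r.recall), fmt(r.f1)]
            )
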