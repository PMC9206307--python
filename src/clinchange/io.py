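"""Readers and writers for the pipeline's file interfaces.

Notes come in as JSONL (one object per line) or CSV with columns
patient_id, trajectory_id, note_id, date (ISO-8601), text.  Outputs are
sentence-level scores as JSONL, summaries as CSV (missing means as empty
fields), and per-stage trace records as JSONL for error analysis.
"""

from __future__ import annotations

import csv
import json
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

from .preprocess import Note
from .scoring import PipelineResult, SentenceScore, SentenceTrace, ThemeSummary

__all__ = [
    "read_notes",
    "write_notes_jsonl",
    "write_scores_jsonl",
    "write_summaries_csv",
    "write_trace_jsonl",
    "write_truth_csv",
]

_NOTE_FIELDS = ("patient_id", "trajectory_id", "note_id", "date", "text")


def _parse_date(value: str) -> date:
    return datetime.strptime(value, "%Y-%m-%d").date()


def _note_from_record(record: dict, where: str) -> Note:
    missing = [f for f in _NOTE_FIELDS if f not in record]
    if missing:
        raise ValueError(f"{where}: missing note fields {missing}")
    return Note(
        patient_id=str(record["patient_id"]),
        trajectory_id=str(record["trajectory_id"]),
        note_id=str(record["note_id"]),
        date=_parse_date(str(record["date"])),
        text=str(record["text"]),
    )


def read_notes(path: str | Path) -> list[Note]:
    path = Path(path)
    notes: list[Note] = []
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with path.open(encoding="utf-8") as fh:
            for line_number, line in enumerate(fh, start=1):
                if line.strip():
                    notes.append(
                        _note_from_record(json.loads(line), f"{path} line {line_number}")
                    )
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for row_number, row in enumerate(csv.DictReader(fh), start=2):
                notes.append(_note_from_record(row, f"{path} row {row_number}"))
    return notes


def write_notes_jsonl(notes: Iterable[Note], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps({
                "patient_id": note.patient_id,
                "trajectory_id": note.trajectory_id,
                "note_id": note.note_id,
                "date": note.date.isoformat(),
                "text": note.text,
            }, ensure_ascii=False) + "\n")


def write_scores_jsonl(scores: Sequence[SentenceScore], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for score in scores:
            fh.write(json.dumps({
                "note_id": score.note_id,
                "sentence_index": score.sentence_index,
                "theme": score.theme,
                "score": score.score,
                "contributing_pairs": list(map(list, score.contributing_pairs)),
                "patient_id": score.patient_id,
                "trajectory_id": score.trajectory_id,
            }, ensure_ascii=False) + "\n")


def write_summaries_csv(summaries: Sequence[ThemeSummary], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["key_kind", "key_id", "theme", "n_theme_sentences",
                         "n_change_sentences", "mean_sentiment"])
        for s in summaries:
            mean = "" if s.mean_sentiment is None else f"{float(s.mean_sentiment):.6g}"
            writer.writerow([s.key_kind, s.key_id, s.theme, s.n_theme_sentences,
                             s.n_change_sentences, mean])


def write_trace_jsonl(traces: Sequence[SentenceTrace], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in traces:
            fh.write(json.dumps({
                "note_id": t.note_id,
                "sentence_index": t.sentence_index,
                "theme": t.theme,
                "stage": t.stage,
                "failed_checks": list(t.failed_checks),
            }) + "\n")


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_scores_jsonl(result.scores, out / "sentence_scores.jsonl")
    write_summaries_csv(result.summaries, out / "summaries.csv")
    write_trace_jsonl(result.sentence_traces, out / "trace.jsonl")
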