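"""Three-level change encoding of structured EHR fields.

Structured admission data (benzodiazepine and other psychiatric medication
prescription counts, juridical status, destination after dismissal) are
encoded as categorical change between the start and end of an admission:
worsened, unchanged or improved.  Each source declares the direction in
which larger values are worse; severity orderings for ordinal sources are
configurable because no canonical ordering exists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scoring import ThemeSummary

__all__ = [
    "StructuredObservation",
    "ChangeCategory",
    "SourceOrdering",
    "DEFAULT_ORDERINGS",
    "encode_change",
    "merge_outcomes",
    "load_observations",
]

WORSENED = "worsened"
UNCHANGED = "unchanged"
IMPROVED = "improved"

KNOWN_SOURCES = (
    "benzodiazepine_prescriptions",
    "other_psychiatric_medication",
    "juridical_status",
    "destination",
)


@dataclass(frozen=True)
class SourceOrdering:
    """How to rank one source's values; larger rank = worse.

    Count sources use numeric comparison directly; ordinal sources rank
    values through ``levels`` (mildest first).
    """

    source: str
    larger_is_worse: bool = True
    levels: tuple[str, ...] = ()

    def rank(self, value) -> float:
        if self.levels:
            try:
                position = self.levels.index(str(value))
            except ValueError as exc:
                raise ValueError(
                    f"value {value!r} not comparable under ordering of "
                    f"source {self.source!r} (levels: {self.levels})"
                ) from exc
            return position if self.larger_is_worse else -position
        try:
            numeric = float(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"value {value!r} of source {self.source!r} is not numeric and "
                f"no ordinal levels are declared"
            ) from exc
        return numeric if self.larger_is_worse else -numeric


#: Shipping defaults; the ordinal severity rankings are explicit assumptions.
DEFAULT_ORDERINGS: dict[str, SourceOrdering] = {
    "benzodiazepine_prescriptions": SourceOrdering("benzodiazepine_prescriptions"),
    "other_psychiatric_medication": SourceOrdering("other_psychiatric_medication"),
    "juridical_status": SourceOrdering(
        "juridical_status", levels=("voluntary", "conditional", "involuntary")
    ),
    "destination": SourceOrdering(
        "destination",
        levels=("home", "sheltered_living", "other_ward", "other_hospital"),
    ),
}


@dataclass(frozen=True)
class StructuredObservation:
    """One source's value at admission start and end for one patient."""

    patient_id: str
    source: str
    value_at_start: object
    value_at_end: object
    ordering: SourceOrdering | None = None

    def resolved_ordering(self) -> SourceOrdering:
        if self.ordering is not None:
            return self.ordering
        if self.source in DEFAULT_ORDERINGS:
            return DEFAULT_ORDERINGS[self.source]
        return SourceOrdering(self.source)


@dataclass(frozen=True)
class ChangeCategory:
    patient_id: str
    source: str
    category: str  # worsened | unchanged | improved

    def __post_init__(self) -> None:
        if self.category not in (WORSENED, UNCHANGED, IMPROVED):
            raise ValueError(f"invalid change category {self.category!r}")


def encode_change(obs: StructuredObservation) -> ChangeCategory:
    """Worsened iff the end value is worse than the start under the source's
    declared ordering; unchanged iff equal; improved otherwise."""
    ordering = obs.resolved_ordering()
    start = ordering.rank(obs.value_at_start)
    end = ordering.rank(obs.value_at_end)
    if end > start:
        category = WORSENED
    elif end == start:
        category = UNCHANGED
    else:
        category = IMPROVED
    return ChangeCategory(patient_id=obs.patient_id, source=obs.source, category=category)


def merge_outcomes(
    summaries: Sequence[ThemeSummary], categories: Sequence[ChangeCategory]
) -> pd.DataFrame:
    """One row per patient: NLP theme means plus structured change categories.

    Missing theme means stay missing (NaN); categorical columns are ordered
    with "worsened" first so it is the natural reference level in
    downstream contrasts.  Input order never affects the output.
    """
    seen: set[tuple[str, str]] = set()
    for category in categories:
        key = (category.patient_id, category.source)
        if key in seen:
            raise ValueError(f"duplicate structured category for {key}")
        seen.add(key)
    seen_summaries: set[tuple[str, str]] = set()
    for summary in summaries:
        key = (summary.key_id, summary.theme)
        if key in seen_summaries:
            raise ValueError(f"duplicate theme summary for {key}")
        seen_summaries.add(key)

    patients = sorted(
        {s.key_id for s in summaries} | {c.patient_id for c in categories}
    )
    themes = sorted({s.theme for s in summaries})
    sources = sorted({c.source for c in categories})
    rows = []
    for patient in patients:
        row: dict[str, object] = {"patient_id": patient}
        for theme in themes:
            mean = next(
                (s.mean_sentiment for s in summaries
                 if s.key_id == patient and s.theme == theme),
                None,
            )
            row[f"{theme}_mean"] = float(mean) if mean is not None else pd.NA
        for source in sources:
            row[source] = next(
                (c.category for c in categories
                 if c.patient_id == patient and c.source == source),
                pd.NA,
            )
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["patient_id"]
                         + [f"{t}_mean" for t in themes] + list(sources))
    category_type = pd.CategoricalDtype([WORSENED, UNCHANGED, IMPROVED])
    for source in sources:
        frame[source] = frame[source].astype(category_type)
    return frame


def load_observations(
    path: str | Path, orderings: Mapping[str, SourceOrdering] | None = None
) -> list[StructuredObservation]:
    """CSV columns: patient_id, source, value_at_start, value_at_end."""
    orderings = dict(DEFAULT_ORDERINGS) | dict(orderings or {})
    observations = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row_number, row in enumerate(csv.DictReader(fh), start=2):
            try:
                observations.append(
                    StructuredObservation(
                        patient_id=row["patient_id"],
                        source=row["source"],
                        value_at_start=row["value_at_start"],
                        value_at_end=row["value_at_end"],
                        ordering=orderings.get(row["source"]),
                    )
                )
            except KeyError as exc:
                raise ValueError(f"{path} row {row_number}: missing column {exc}") from exc
    return observations
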