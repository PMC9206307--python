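"""The five-check context filter (pipeline step 4).

Candidate pairs are rejected when their phrases occur in an invalid
context.  Four checks use trigger/scope semantics in the style of the
ConText algorithm: a trigger phrase (from a per-language rule file) opens a
scope running forward and/or backward up to a token window or the sentence
boundary, truncated at scope-terminator phrases; a check fails when the
scope covers the relevant match.  The fifth check tests whether the change
grammatically concerns the theme, via dependency-path distance when a
parsing backend is available and a token-window rule otherwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .filters import CandidatePair, Match
from .preprocess import AnnotatedSentence

__all__ = [
    "ContextRule",
    "ContextRuleSet",
    "ContextVerdict",
    "LinkageConfig",
    "load_context_rules",
    "check_negation",
    "check_hypothetical",
    "check_experiencer",
    "check_temporality",
    "check_change_concerns_theme",
    "apply_context_filter",
    "CHECK_NAMES",
]

KIND_NEGATION = "negation"
KIND_HYPOTHETICAL = "hypothetical"
KIND_NONPATIENT = "non-patient-experiencer"
KIND_NONCURRENT = "non-current"
KIND_TERMINATOR = "terminator"

_TRIGGER_KINDS = (KIND_NEGATION, KIND_HYPOTHETICAL, KIND_NONPATIENT, KIND_NONCURRENT)

CHECK_NAMES = (
    "current",
    "not_hypothetical",
    "concerns_patient",
    "not_negated",
    "change_concerns_theme",
)

DEFAULT_TERMINATORS = ("but", "however", ";")


class ContextRuleError(ValueError):
    pass


@dataclass(frozen=True)
class ContextRule:
    """A trigger phrase opening an invalid-context scope."""

    trigger: str
    kind: str
    scope: str = "forward"  # forward | backward | bidirectional
    window: int | None = None  # token count; None = sentence-bounded

    def __post_init__(self) -> None:
        if not self.trigger.strip():
            raise ContextRuleError("trigger must be non-empty")
        object.__setattr__(self, "trigger", " ".join(self.trigger.casefold().split()))
        if self.kind not in _TRIGGER_KINDS:
            raise ContextRuleError(f"unknown rule kind {self.kind!r}")
        if self.scope not in ("forward", "backward", "bidirectional"):
            raise ContextRuleError(f"unknown scope {self.scope!r}")
        if self.window is not None and self.window < 1:
            raise ContextRuleError("window must be >= 1 or sentence-bounded (None)")

    @property
    def trigger_tokens(self) -> tuple[str, ...]:
        return tuple(self.trigger.split())


@dataclass(frozen=True)
class ContextRuleSet:
    """All context rules for one language plus its scope terminators."""

    rules: tuple[ContextRule, ...] = ()
    terminators: tuple[str, ...] = DEFAULT_TERMINATORS

    def of_kind(self, kind: str) -> tuple[ContextRule, ...]:
        return tuple(r for r in self.rules if r.kind == kind)

    @classmethod
    def empty(cls) -> "ContextRuleSet":
        """Permissive rule set: checks 1-4 pass for every pair."""
        return cls(rules=(), terminators=DEFAULT_TERMINATORS)


def load_context_rules(path: str | Path) -> ContextRuleSet:
    """Load a TSV rule file: columns trigger, kind, scope, window.

    ``window`` empty or "sentence" means sentence-bounded.  Rows with kind
    "terminator" extend the scope-terminator list instead of adding a
    trigger.
    """
    path = Path(path)
    rules: list[ContextRule] = []
    terminators: list[str] = list(DEFAULT_TERMINATORS)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "trigger" not in reader.fieldnames:
            raise ContextRuleError(f"{path}: missing header with 'trigger' column")
        for row_number, row in enumerate(reader, start=2):
            kind = (row.get("kind") or "").strip()
            trigger = (row.get("trigger") or "").strip()
            if kind == KIND_TERMINATOR:
                if trigger and trigger.casefold() not in terminators:
                    terminators.append(trigger.casefold())
                continue
            raw_window = (row.get("window") or "").strip().lower()
            window = None if raw_window in ("", "sentence") else int(raw_window)
            try:
                rules.append(
                    ContextRule(trigger=trigger, kind=kind,
                                scope=(row.get("scope") or "forward").strip(),
                                window=window)
                )
            except ContextRuleError as exc:
                raise ContextRuleError(f"{path} row {row_number}: {exc}") from exc
    return ContextRuleSet(rules=tuple(rules), terminators=tuple(terminators))


# ---------------------------------------------------------------------------
# Scope computation

def _surfaces(sentence: AnnotatedSentence) -> list[str]:
    return [t.surface.casefold() for t in sentence.tokens]


def _phrase_positions(surfaces: list[str], phrase: tuple[str, ...]) -> list[tuple[int, int]]:
    width = len(phrase)
    hits = []
    for i in range(len(surfaces) - width + 1):
        if tuple(surfaces[i : i + width]) == phrase:
            hits.append((i, i + width))
    return hits


def _scope_tokens(
    sentence: AnnotatedSentence, rule: ContextRule, terminators: tuple[str, ...]
) -> set[int]:
    """Token indices covered by any occurrence of the rule's trigger."""
    surfaces = _surfaces(sentence)
    terminator_phrases = [tuple(t.casefold().split()) for t in terminators]
    terminator_starts = {
        start
        for phrase in terminator_phrases
        for start, _ in _phrase_positions(surfaces, phrase)
    }
    n = len(surfaces)
    covered: set[int] = set()
    for t_start, t_end in _phrase_positions(surfaces, rule.trigger_tokens):
        if rule.scope in ("forward", "bidirectional"):
            end = n if rule.window is None else min(n, t_end + rule.window)
            for i in range(t_end, end):
                if i in terminator_starts:
                    break
                covered.add(i)
        if rule.scope in ("backward", "bidirectional"):
            start = 0 if rule.window is None else max(0, t_start - rule.window)
            for i in range(t_start - 1, start - 1, -1):
                if i in terminator_starts:
                    break
                covered.add(i)
    return covered


def _scoped(
    sentence: AnnotatedSentence,
    rules: ContextRuleSet,
    kind: str,
    matches: tuple[Match, ...],
) -> bool:
    """True when any trigger of the given kind scopes any of the matches."""
    match_tokens = {i for m in matches for i in range(*m.span)}
    for rule in rules.of_kind(kind):
        if _scope_tokens(sentence, rule, rules.terminators) & match_tokens:
            return True
    return False


# ---------------------------------------------------------------------------
# The five checks; each returns "pass" or "fail".

def check_negation(
    sentence: AnnotatedSentence, pair: CandidatePair, rules: ContextRuleSet
) -> str:
    """Fail when a negation trigger scopes the change or theme match: a
    negated change word removes both it and the corresponding theme word."""
    hit = _scoped(sentence, rules, KIND_NEGATION, (pair.theme_match, pair.change_match))
    return "fail" if hit else "pass"


def check_hypothetical(
    sentence: AnnotatedSentence, pair: CandidatePair, rules: ContextRuleSet
) -> str:
    """Fail when a conditional/possibility trigger scopes either match."""
    hit = _scoped(sentence, rules, KIND_HYPOTHETICAL, (pair.theme_match, pair.change_match))
    return "fail" if hit else "pass"


def check_experiencer(
    sentence: AnnotatedSentence, pair: CandidatePair, rules: ContextRuleSet
) -> str:
    """Fail when the state belongs to someone other than the patient.

    The patient is the assumed experiencer of clinical notes, so the check
    passes by default and fails only when a non-patient trigger (family or
    clinician subject phrase) scopes the theme match.
    """
    hit = _scoped(sentence, rules, KIND_NONPATIENT, (pair.theme_match,))
    return "fail" if hit else "pass"


def check_temporality(
    sentence: AnnotatedSentence, pair: CandidatePair, rules: ContextRuleSet
) -> str:
    """The "current" check: fail when a history/future marker scopes either match."""
    hit = _scoped(sentence, rules, KIND_NONCURRENT, (pair.theme_match, pair.change_match))
    return "fail" if hit else "pass"


@dataclass(frozen=True)
class LinkageConfig:
    """Parameters of the change-concerns-theme check.

    ``dep_path_bound`` caps the dependency-path length between the matches
    when a parse is available; ``token_window`` caps the token gap in the
    fallback.  Clause delimiters: ';' always splits clauses (nursing notes
    chain independent statements with semicolons); a coordinating
    conjunction or ',' splits only when a finite verb follows it later in
    the sentence.
    """

    dep_path_bound: int = 3
    token_window: int = 6
    coord_conjunctions: tuple[str, ...] = ("and", "but", "or", "nor")
    hard_delimiters: tuple[str, ...] = (";",)
    soft_delimiters: tuple[str, ...] = (",",)
    clause_deprels: tuple[str, ...] = (
        "cc", "conj", "ccomp", "advcl", "acl", "parataxis", "csubj",
    )


def _dependency_path(sentence: AnnotatedSentence, a: int, b: int) -> list[int] | None:
    """Token indices on the undirected head-arc path from a to b, inclusive."""
    def ancestors(i: int) -> list[int]:
        chain = [i]
        seen = {i}
        while sentence.tokens[chain[-1]].deprel != "root":
            nxt = sentence.tokens[chain[-1]].head
            if nxt in seen:
                return chain
            seen.add(nxt)
            chain.append(nxt)
        return chain

    up_a, up_b = ancestors(a), ancestors(b)
    set_b = {i: d for d, i in enumerate(up_b)}
    for depth_a, node in enumerate(up_a):
        if node in set_b:
            return up_a[: depth_a + 1] + up_b[: set_b[node]][::-1]
    return None


def _finite_verb_after(sentence: AnnotatedSentence, index: int) -> bool:
    return any(t.pos in ("VERB", "AUX") for t in sentence.tokens[index + 1 :])


def check_change_concerns_theme(
    sentence: AnnotatedSentence,
    pair: CandidatePair,
    config: LinkageConfig | None = None,
) -> str:
    """Pass iff the change match is syntactically linked to the theme match.

    Distinguishes "anxiety symptoms increased" (linked) from "We increased
    the medication doses but the patient's anxiety did not respond" (the
    change sits in a different clause).
    """
    config = config or LinkageConfig()
    theme_span, change_span = pair.theme_match.span, pair.change_match.span
    if sentence.parsed:
        best: list[int] | None = None
        for a in range(*theme_span):
            for b in range(*change_span):
                path = _dependency_path(sentence, a, b)
                if path is not None and (best is None or len(path) < len(best)):
                    best = path
        if best is None or len(best) - 1 > config.dep_path_bound:
            return "fail"
        for node in best[1:-1]:
            if sentence.tokens[node].deprel in config.clause_deprels:
                return "fail"
        return "pass"
    # Fallback: token distance with clause-delimiter scan.
    gap = pair.theme_match.distance_to(pair.change_match)
    if gap > config.token_window:
        return "fail"
    lo = min(theme_span[1], change_span[1])
    hi = max(theme_span[0], change_span[0])
    for i in range(lo, hi):
        word = sentence.tokens[i].surface.casefold()
        if word in config.hard_delimiters:
            return "fail"
        if word in config.coord_conjunctions or word in config.soft_delimiters:
            if _finite_verb_after(sentence, i):
                return "fail"
    return "pass"


@dataclass(frozen=True)
class ContextVerdict:
    """Check-by-check outcome for one candidate pair.

    ``accepted`` is true exactly when all five checks pass.
    """

    pair: CandidatePair
    checks: dict = field(default_factory=dict)
    accepted: bool = False

    def __post_init__(self) -> None:
        expected = all(v == "pass" for v in self.checks.values()) and set(
            self.checks
        ) == set(CHECK_NAMES)
        if self.accepted != expected:
            raise ValueError("accepted flag must equal the conjunction of the five checks")


def apply_context_filter(
    sentence: AnnotatedSentence,
    pairs: list[CandidatePair],
    rules: ContextRuleSet,
    linkage: LinkageConfig | None = None,
) -> list[ContextVerdict]:
    """Run the five checks on every pair; order-preserving, pairs independent."""
    verdicts = []
    for pair in pairs:
        checks = {
            "current": check_temporality(sentence, pair, rules),
            "not_hypothetical": check_hypothetical(sentence, pair, rules),
            "concerns_patient": check_experiencer(sentence, pair, rules),
            "not_negated": check_negation(sentence, pair, rules),
            "change_concerns_theme": check_change_concerns_theme(sentence, pair, linkage),
        }
        verdicts.append(
            ContextVerdict(
                pair=pair,
                checks=checks,
                accepted=all(v == "pass" for v in checks.values()),
            )
        )
    return verdicts
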