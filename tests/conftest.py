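from datetime import date

import pytest

from clinchange import (
    ContextRuleSet,
    Lexicon,
    LexiconEntry,
    Note,
    fixture_lexicon,
    fixture_rules,
)
from clinchange.context import ContextRule


def make_note(text: str, patient="p1", trajectory="p1-T1", note_id="n1",
              when=date(2020, 1, 1)) -> Note:
    return Note(patient_id=patient, trajectory_id=trajectory, note_id=note_id,
                date=when, text=text)


@pytest.fixture
def note_factory():
    return make_note


@pytest.fixture
def symptoms_lexicon() -> Lexicon:
    return Lexicon((
        LexiconEntry("anxiety", "theme:symptoms", -1),
        LexiconEntry("anxious", "theme:symptoms", -1),
        LexiconEntry("sad", "theme:symptoms", -1),
        LexiconEntry("calmness", "theme:symptoms", 1),
        LexiconEntry("more", "change", 1),
        LexiconEntry("less", "change", -1),
        LexiconEntry("increased", "change", 1),
        LexiconEntry("improve", "change", 1),
        LexiconEntry("improved", "change", 1),
    ))


@pytest.fixture
def english_lexicon() -> Lexicon:
    return fixture_lexicon()


@pytest.fixture
def english_rules() -> ContextRuleSet:
    return fixture_rules()


@pytest.fixture
def minimal_rules() -> ContextRuleSet:
    return ContextRuleSet(rules=(
        ContextRule("not", "negation"),
        ContextRule("no", "negation"),
        ContextRule("if", "hypothetical"),
        ContextRule("possibly", "hypothetical"),
        ContextRule("mother", "non-patient-experiencer"),
        ContextRule("sister", "non-patient-experiencer"),
        ContextRule("years ago", "non-current", scope="bidirectional"),
        ContextRule("previously", "non-current"),
    ))
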