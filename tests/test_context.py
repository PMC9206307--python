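import itertools

import pytest

from clinchange import context as ctx
from clinchange.context import (
    ContextRule,
    ContextRuleError,
    ContextRuleSet,
    ContextVerdict,
    LinkageConfig,
    apply_context_filter,
    check_change_concerns_theme,
    check_experiencer,
    check_hypothetical,
    check_negation,
    check_temporality,
    load_context_rules,
)
from clinchange.filters import change_filter, pair_candidates, theme_filter
from clinchange.lexicon import Lexicon, LexiconEntry
from clinchange.preprocess import segment


def _pair_from(note_factory, lexicon, text, theme=None):
    (sentence,) = segment(note_factory(text))
    themes = theme_filter(sentence, lexicon)
    changes = change_filter(sentence, lexicon)
    pairs = pair_candidates(themes, changes)
    if theme is not None:
        pairs = [p for p in pairs if p.theme == theme]
    assert pairs, f"no candidate pair in {text!r}"
    return sentence, pairs[0]


@pytest.fixture
def mood_lexicon():
    return Lexicon((
        LexiconEntry("mood", "theme:wellbeing", 1),
        LexiconEntry("anxiety", "theme:symptoms", -1),
        LexiconEntry("hungry", "theme:wellbeing", -1),
        LexiconEntry("sadness", "theme:symptoms", -1),
        LexiconEntry("improve", "change", 1),
        LexiconEntry("improved", "change", 1),
        LexiconEntry("increased", "change", 1),
        LexiconEntry("more", "change", 1),
    ))


class TestNegation:
    def test_negated_change_word_fails(self, note_factory, mood_lexicon, minimal_rules):
        sentence, pair = _pair_from(note_factory, mood_lexicon, "mood did not improve")
        assert check_negation(sentence, pair, minimal_rules) == "fail"

    def test_no_trigger_passes(self, note_factory, mood_lexicon, minimal_rules):
        sentence, pair = _pair_from(note_factory, mood_lexicon, "mood improved")
        assert check_negation(sentence, pair, minimal_rules) == "pass"

    def test_scope_terminated_by_but(self, note_factory, mood_lexicon, minimal_rules):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "not hungry, but anxiety increased",
            theme="symptoms",
        )
        assert check_negation(sentence, pair, minimal_rules) == "pass"

    def test_scope_termination_matches_enumeration_oracle(
        self, note_factory, mood_lexicon, minimal_rules
    ):
        """Trigger scope = tokens after the trigger up to the first terminator,
        independently enumerated."""
        text = "not hungry, but anxiety increased"
        (sentence,) = segment(note_factory(text))
        surfaces = [t.surface.casefold() for t in sentence.tokens]
        trigger_at = surfaces.index("not")
        scope = set()
        for i in range(trigger_at + 1, len(surfaces)):
            if surfaces[i] in ("but", "however", ";"):
                break
            scope.add(i)
        themes = theme_filter(sentence, mood_lexicon)
        changes = change_filter(sentence, mood_lexicon)
        for pair in pair_candidates(themes, changes):
            tokens = set(range(*pair.theme_match.span)) | set(
                range(*pair.change_match.span)
            )
            expected = "fail" if tokens & scope else "pass"
            assert check_negation(sentence, pair, minimal_rules) == expected


class TestExperiencer:
    def test_family_member_subject_fails(self, note_factory, mood_lexicon, minimal_rules):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "Mother reports she herself felt more anxiety"
        )
        assert check_experiencer(sentence, pair, minimal_rules) == "fail"

    def test_patient_is_default_experiencer(self, note_factory, mood_lexicon,
                                            minimal_rules):
        sentence, pair = _pair_from(note_factory, mood_lexicon, "mood improved")
        assert check_experiencer(sentence, pair, minimal_rules) == "pass"

    def test_possessive_family_experiencer_fails(self, note_factory, mood_lexicon,
                                                 minimal_rules):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "Sister 's sadness increased"
        )
        assert check_experiencer(sentence, pair, minimal_rules) == "fail"


class TestTemporality:
    def test_history_marker_fails(self, note_factory, mood_lexicon, minimal_rules):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "Years ago anxiety increased sharply"
        )
        assert check_temporality(sentence, pair, minimal_rules) == "fail"

    def test_current_statement_passes(self, note_factory, mood_lexicon, minimal_rules):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "Today, anxiety symptoms increased"
        )
        assert check_temporality(sentence, pair, minimal_rules) == "pass"

    def test_trigger_outside_window_passes(self, note_factory, mood_lexicon):
        rules = ContextRuleSet(rules=(
            ContextRule("previously", "non-current", scope="forward", window=2),
        ))
        sentence, pair = _pair_from(
            note_factory, mood_lexicon,
            "previously stable on the ward and now anxiety increased",
        )
        # both matches sit more than 2 tokens after the trigger
        assert check_temporality(sentence, pair, rules) == "pass"


class TestHypothetical:
    def test_conditional_fails(self, note_factory, mood_lexicon, minimal_rules):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "if anxiety increased, call us"
        )
        assert check_hypothetical(sentence, pair, minimal_rules) == "fail"

    def test_plain_statement_passes(self, note_factory, mood_lexicon, minimal_rules):
        sentence, pair = _pair_from(note_factory, mood_lexicon, "anxiety increased")
        assert check_hypothetical(sentence, pair, minimal_rules) == "pass"

    def test_possibility_marker_before_change_fails(self, note_factory, mood_lexicon,
                                                    minimal_rules):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "anxiety possibly increased"
        )
        assert check_hypothetical(sentence, pair, minimal_rules) == "fail"


class TestLinkage:
    def test_change_governing_theme_passes(self, note_factory, mood_lexicon):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "anxiety symptoms increased"
        )
        assert check_change_concerns_theme(sentence, pair) == "pass"

    def test_change_in_other_clause_fails(self, note_factory, mood_lexicon):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon,
            "We increased the medication doses but the patient 's anxiety did not respond",
        )
        assert check_change_concerns_theme(sentence, pair) == "fail"

    def test_adjacent_tokens_pass(self, note_factory, mood_lexicon):
        sentence, pair = _pair_from(note_factory, mood_lexicon, "more anxiety")
        assert check_change_concerns_theme(sentence, pair) == "pass"

    def test_semicolon_always_splits_clauses(self, note_factory, mood_lexicon):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "anxiety noted ; improved hygiene",
            theme="symptoms",
        )
        assert check_change_concerns_theme(sentence, pair) == "fail"

    def test_window_bound_configurable(self, note_factory, mood_lexicon):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "anxiety on the ward this morning increased"
        )
        assert check_change_concerns_theme(sentence, pair,
                                           LinkageConfig(token_window=6)) == "pass"
        assert check_change_concerns_theme(sentence, pair,
                                           LinkageConfig(token_window=3)) == "fail"

    def test_dependency_path_used_when_parsed(self, note_factory, mood_lexicon):
        from dataclasses import replace
        sentence, pair = _pair_from(note_factory, mood_lexicon,
                                    "anxiety symptoms increased")
        parsed = replace(sentence, parsed=True)
        # flat tree from the rule annotator: root is "increased"; path length 1
        assert check_change_concerns_theme(parsed, pair) == "pass"
        tight = LinkageConfig(dep_path_bound=0)
        assert check_change_concerns_theme(parsed, pair, tight) == "fail"


class TestApplyFilter:
    def test_accept_is_conjunction_of_all_32_combinations(
        self, note_factory, mood_lexicon, minimal_rules, monkeypatch
    ):
        """Exhaustively mock every pass/fail pattern of the five checks."""
        sentence, pair = _pair_from(note_factory, mood_lexicon, "more anxiety")
        checker_names = [
            "check_temporality", "check_hypothetical", "check_experiencer",
            "check_negation", "check_change_concerns_theme",
        ]
        for pattern in itertools.product(("pass", "fail"), repeat=5):
            for name, outcome in zip(checker_names, pattern):
                monkeypatch.setattr(
                    ctx, name,
                    lambda *args, _outcome=outcome, **kwargs: _outcome,
                )
            (verdict,) = ctx.apply_context_filter(sentence, [pair], minimal_rules)
            assert verdict.accepted == all(o == "pass" for o in pattern)
            monkeypatch.undo()

    def test_empty_rules_leave_only_linkage_active(self, note_factory, mood_lexicon):
        sentence, pair = _pair_from(
            note_factory, mood_lexicon, "if not anxiety previously increased"
        )
        (verdict,) = apply_context_filter(sentence, [pair], ContextRuleSet.empty())
        for name in ("current", "not_hypothetical", "concerns_patient", "not_negated"):
            assert verdict.checks[name] == "pass"

    def test_verdicts_independent_across_pairs(self, note_factory, mood_lexicon,
                                               minimal_rules):
        (sentence,) = segment(
            note_factory("not hungry, but anxiety increased")
        )
        themes = theme_filter(sentence, mood_lexicon)
        changes = change_filter(sentence, mood_lexicon)
        pairs = pair_candidates(themes, changes)
        verdicts = apply_context_filter(sentence, pairs, minimal_rules)
        assert [v.pair for v in verdicts] == pairs
        by_theme = {v.pair.theme: v for v in verdicts}
        assert by_theme["wellbeing"].accepted is False  # "hungry" negated
        assert by_theme["symptoms"].accepted is True

    def test_empty_pair_list(self, note_factory, mood_lexicon, minimal_rules):
        (sentence,) = segment(note_factory("hello there"))
        assert apply_context_filter(sentence, [], minimal_rules) == []

    def test_verdict_flag_must_match_checks(self, note_factory, mood_lexicon,
                                            minimal_rules):
        sentence, pair = _pair_from(note_factory, mood_lexicon, "more anxiety")
        (verdict,) = apply_context_filter(sentence, [pair], minimal_rules)
        with pytest.raises(ValueError):
            ContextVerdict(pair=pair, checks=dict(verdict.checks),
                           accepted=not verdict.accepted)


class TestRuleFiles:
    def test_load_tsv_with_terminators(self, tmp_path):
        path = tmp_path / "rules.tsv"
        path.write_text(
            "trigger\tkind\tscope\twindow\n"
            "not\tnegation\tforward\tsentence\n"
            "years ago\tnon-current\tbidirectional\t5\n"
            "but\tterminator\t\t\n",
            encoding="utf-8",
        )
        rules = load_context_rules(path)
        assert len(rules.rules) == 2
        assert rules.of_kind("non-current")[0].window == 5
        assert "but" in rules.terminators

    def test_bad_kind_raises_with_row(self, tmp_path):
        path = tmp_path / "rules.tsv"
        path.write_text("trigger\tkind\tscope\twindow\nfoo\tbogus\tforward\t\n",
                        encoding="utf-8")
        with pytest.raises(ContextRuleError, match="row 2"):
            load_context_rules(path)

    def test_window_must_be_positive(self):
        with pytest.raises(ContextRuleError):
            ContextRule("not", "negation", window=0)

    def test_dutch_starter_rules_load(self):
        from clinchange import fixture_rules
        rules = fixture_rules("nl")
        assert rules.of_kind("negation")
        assert "maar" in rules.terminators
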