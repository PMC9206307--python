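import random
from dataclasses import replace
from fractions import Fraction

import pytest

from clinchange import (
    Lexicon,
    LexiconEntry,
    SentenceScore,
    aggregate,
    fixture_lexicon,
    fixture_rules,
    generate,
    GeneratorConfig,
    run_pipeline,
    score_sentence,
)
from clinchange.context import ContextRuleSet, apply_context_filter
from clinchange.filters import change_filter, pair_candidates, theme_filter
from clinchange.preprocess import segment


def _score_text(note_factory, lexicon, text, rules=None):
    result = run_pipeline([note_factory(text)], lexicon,
                          rules or ContextRuleSet.empty())
    return {(s.theme): s.score for s in result.scores}


class TestSentenceScoring:
    def test_increase_of_negative_phrase(self, note_factory):
        lexicon = Lexicon((LexiconEntry("anxiety", "theme:symptoms", -1),
                           LexiconEntry("more", "change", 1)))
        assert _score_text(note_factory, lexicon, "more anxiety") == {"symptoms": -1}

    def test_increase_of_positive_phrase(self, note_factory):
        lexicon = Lexicon((LexiconEntry("participation", "theme:social", 1),
                           LexiconEntry("improved", "change", 1)))
        assert _score_text(note_factory, lexicon, "participation improved") == {"social": 1}

    def test_multiple_pairs_add(self, note_factory):
        lexicon = Lexicon((LexiconEntry("anxious", "theme:symptoms", -1),
                           LexiconEntry("sad", "theme:symptoms", -1),
                           LexiconEntry("more", "change", 1)))
        assert _score_text(
            note_factory, lexicon, "The patient was more anxious and sad"
        ) == {"symptoms": -2}

    def test_decrease_flips_sign(self, note_factory):
        lexicon = Lexicon((LexiconEntry("energy", "theme:wellbeing", 1),
                           LexiconEntry("less", "change", -1)))
        assert _score_text(note_factory, lexicon, "Had less energy") == {"wellbeing": -1}

    def test_no_accepted_pair_emits_nothing(self, note_factory, symptoms_lexicon):
        (sentence,) = segment(note_factory("anxiety discussed"))
        themes = theme_filter(sentence, symptoms_lexicon)
        changes = change_filter(sentence, symptoms_lexicon)
        verdicts = apply_context_filter(
            sentence, pair_candidates(themes, changes), ContextRuleSet.empty()
        )
        assert score_sentence(verdicts) == []

    def test_score_invariant_enforced(self):
        with pytest.raises(ValueError):
            SentenceScore("n", 0, "symptoms", 5, ((-1, 1),))


class TestAggregate:
    def _scores(self, values, patient="p1"):
        out = []
        for i, value in enumerate(values):
            sign = -1 if value < 0 else 1
            pairs = tuple((sign, 1) for _ in range(abs(value)))
            out.append(SentenceScore(f"n{i}", 0, "symptoms", value, pairs,
                                     patient_id=patient, trajectory_id=f"{patient}-T1"))
        return out

    def test_worked_example_mean_one_third(self):
        summary = aggregate(self._scores([-2, 1, 2]), "patient", "symptoms")
        assert summary.mean_sentiment == Fraction(1, 3)
        assert summary.n_change_sentences == 3

    def test_empty_group_mean_undefined_not_zero(self):
        summary = aggregate([], "patient", "symptoms", n_theme_sentences=4,
                            key_id="p9")
        assert summary.mean_sentiment is None
        assert summary.key_id == "p9"

    def test_constant_scores(self):
        assert aggregate(self._scores([-1, -1]), "patient", "symptoms"
                         ).mean_sentiment == Fraction(-1)

    def test_mixed_keys_rejected(self):
        scores = self._scores([1], "pa") + self._scores([1], "pb")
        with pytest.raises(ValueError, match="mixed"):
            aggregate(scores, "patient", "symptoms")

    def test_exact_rational_arithmetic(self):
        summary = aggregate(self._scores([1, 1, 1, -1, -1, -1, 1]), "patient",
                            "symptoms")
        assert summary.mean_sentiment == Fraction(1, 7)


@pytest.fixture(scope="module")
def corpus():
    config = GeneratorConfig(n_patients=15, seed=11)
    return generate(config)


class TestPipelineProperties:
    def test_empty_note_list(self):
        result = run_pipeline([], fixture_lexicon(), fixture_rules())
        assert result.scores == [] and result.summaries == []

    def test_permutation_invariance(self, corpus):
        """Shuffling note order leaves all summaries unchanged."""
        notes, _ = corpus
        lexicon, rules = fixture_lexicon(), fixture_rules()
        base = run_pipeline(notes, lexicon, rules)
        shuffled = list(notes)
        random.Random(5).shuffle(shuffled)
        other = run_pipeline(shuffled, lexicon, rules)
        key = lambda s: (s.key_kind, s.key_id, s.theme)
        assert sorted(base.summaries, key=key) == sorted(other.summaries, key=key)

    def test_sign_flip(self, corpus):
        """Negating every theme polarity negates every score and mean."""
        notes, _ = corpus
        lexicon, rules = fixture_lexicon(), fixture_rules()
        flipped = Lexicon(tuple(
            replace(e, polarity=-e.polarity) if not e.is_change else e
            for e in lexicon.entries
        ))
        base = run_pipeline(notes, lexicon, rules)
        negated = run_pipeline(notes, flipped, rules)
        base_scores = {(s.note_id, s.sentence_index, s.theme): s.score
                       for s in base.scores}
        flip_scores = {(s.note_id, s.sentence_index, s.theme): s.score
                       for s in negated.scores}
        assert base_scores.keys() == flip_scores.keys()
        assert all(flip_scores[k] == -v for k, v in base_scores.items())
        base_means = {(s.key_kind, s.key_id, s.theme): s.mean_sentiment
                      for s in base.summaries}
        flip_means = {(s.key_kind, s.key_id, s.theme): s.mean_sentiment
                      for s in negated.summaries}
        for key, mean in base_means.items():
            if mean is None:
                assert flip_means[key] is None
            else:
                assert flip_means[key] == -mean

    def test_score_conservation(self, corpus):
        """Sum over groups of mean × n equals the sum of sentence scores."""
        notes, _ = corpus
        result = run_pipeline(notes, fixture_lexicon(), fixture_rules())
        for theme in fixture_lexicon().themes:
            total = sum(s.score for s in result.scores if s.theme == theme)
            for kind in ("patient", "trajectory"):
                recomposed = sum(
                    (s.mean_sentiment * s.n_change_sentences
                     for s in result.summaries
                     if s.key_kind == kind and s.theme == theme
                     and s.mean_sentiment is not None),
                    Fraction(0),
                )
                assert recomposed == total

    def test_deterministic_for_fixed_inputs(self, corpus):
        notes, _ = corpus
        lexicon, rules = fixture_lexicon(), fixture_rules()
        a = run_pipeline(notes, lexicon, rules)
        b = run_pipeline(notes, lexicon, rules)
        assert a.scores == b.scores
        assert a.summaries == b.summaries
        assert a.sentence_traces == b.sentence_traces

    def test_stage_counts_are_monotone(self, corpus):
        notes, _ = corpus
        result = run_pipeline(notes, fixture_lexicon(), fixture_rules())
        for counts in result.stage_counts.values():
            assert (counts.n_sentences >= counts.n_theme_pass
                    >= counts.n_change_pass >= counts.n_accepted >= 0)


class TestFigureTrace:
    def test_three_sentence_hypothetical_note(self, note_factory):
        """Sentence 1 dies at the change filter, sentence 3 at negation;
        only sentence 2 is scored."""
        lexicon = Lexicon(fixture_lexicon().entries
                          + (LexiconEntry("improve", "change", 1),))
        note = note_factory(
            "Patient mentioned anxiety during the day. "
            "Participation improved in the group. "
            "Energy did not improve today."
        )
        result = run_pipeline([note], lexicon, fixture_rules())
        stages = {(t.sentence_index, t.theme): (t.stage, t.failed_checks)
                  for t in result.sentence_traces}
        assert stages[(0, "symptoms")] == ("step3", ())
        assert stages[(1, "social")] == ("scored", ())
        assert stages[(2, "wellbeing")][0] == "step4"
        assert "not_negated" in stages[(2, "wellbeing")][1]
        assert [(s.sentence_index, s.theme, s.score) for s in result.scores] == [
            (1, "social", 1)
        ]
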