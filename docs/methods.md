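# Methods

## Model

`clinchange` implements a semi-rule-based sentence classifier and scorer
for clinical free text. Its unit of analysis is the sentence; its output
is, per theme, an integer sentiment per scored sentence and an exact
rational mean per patient or trajectory.

The underlying model of a "moment of change" is deliberately simple and
fully inspectable:

- a **theme phrase** asserts that a clinical dimension is being discussed,
  and carries a fixed connotation polarity in {−1, +1};
- a **change cue** asserts that the dimension moved, and carries a fixed
  direction in {−1, +1}; a comparative adjective form is a change cue with
  direction +1 (*"angrier"* = more anger — the sign comes from the theme
  phrase, not the comparative);
- a sentence describes a valid change when a theme phrase and a change cue
  co-occur in a context that is current, factual, about the patient,
  non-negated, and in which the change grammatically concerns the theme;
- the score of an accepted (theme, change) pair is the product
  polarity × direction; multiple pairs in one sentence add.

Assumptions worth stating: polarities are context-free (no irony,
no scale reversal inside the sentence); a change cue licenses every theme
phrase it is paired with; sentences are independent (no cross-sentence
anaphora or discourse structure); the patient is the default experiencer
of a clinical note unless a trigger says otherwise.

## Pairing rule

When a sentence holds several theme phrases and several change cues, each
theme match is paired with its **nearest** change cue by token distance,
ties broken leftmost, and one cue may serve several theme matches. This
reproduces the canonical two-adjective example (one *more* licensing both
*anxious* and *sad*, total −2). A token matched as a theme phrase may not
simultaneously act as the change cue of its own pair; this forbids the
degenerate self-pair that a comparative theme adjective would otherwise
form.

## Context checks

Checks 1–4 (current, not hypothetical, concerns patient, not negated) use
trigger/scope semantics in the style of the ConText algorithm: a trigger
phrase from a per-language TSV opens a scope forward and/or backward, up
to a token window or the sentence boundary, truncated at scope-terminator
phrases (default *but*, *however*, `;`). A check fails when the scope
covers the change match or the theme match (experiencer: theme match
only). Negation of either member kills the whole pair. Trigger
inventories are data, not code; the shipped English and Dutch sets are
small starter sets, not validated clinical resources, and real deployments
should curate their own.

Check 5 (change concerns theme) is structural. With a parsing backend it
requires an undirected dependency path of length ≤ `dep_path_bound`
(default 3) between the matches with no clausal relation on the path.
With the default rule-based annotator it falls back to a token rule: gap ≤
`token_window` (default 6) and no clause delimiter between the matches. A
semicolon always delimits clauses — nursing notes chain independent,
often verb-less statements with semicolons, and treating `;` as
conditional would let pairs leak across statement boundaries. A
coordinating conjunction or comma delimits only when a finite verb occurs
later in the sentence, which keeps *"more anxious and sad"* in one clause
while splitting *"We increased the medication doses but the patient's
anxiety did not respond"*. All three knobs are `LinkageConfig` fields.

## Annotation backend

The pipeline depends only on the `Token` contract (surface, lemma, POS,
degree, head, deprel, offsets), so any tagger/parser can be injected via
the `Annotator` protocol. The shipped `RuleBasedAnnotator` is a
deterministic table/suffix tagger: closed-class word lists, a
language-configurable comparative/superlative suffix table (`-er`/`-ier`,
`-est`/`-iest`) with an irregular-form table and an exclusion list for
non-gradable `-er` nouns (*anger*, *mother*, …), and a minimum stem length
of 4 to reject short false stems. It emits a flat dependency tree and
declares `provides_dependencies = False`, which routes the linkage check
to its token-window fallback. Lemma-mode lexicon matching exists to
recover inflectional variants a surface-form list misses (the documented
failure mode of surface-only change lists is missed verb conjugations),
but the default remains exact surface matching.

Sentence splitting treats terminal punctuation and newlines as
boundaries; short newline-terminated lines are common in nursing notes
and are treated as sentences. Bullet markers and headings are not treated
specially beyond this.

## Aggregation

Per group (trajectory by default — one inpatient admission episode — with
patient-level also emitted), the theme summary reports the number of
sentences containing a theme phrase, the number with at least one accepted
pair, and the mean sentiment over the latter as an exact
`fractions.Fraction`. An empty group's mean is `None`, never 0: absence
of observed change is missing data, not a neutral observation.

## Evaluation harness

A sentence is predicted *accept* for a theme exactly when the full
pipeline scores it for that theme. Confusion counts are tallied per theme
against human accept/reject labels; accuracy, precision, recall and F1
follow the standard definitions, with zero-denominator ratios reported as
missing rather than 0 or 1, so degenerate validation sets cannot silently
inflate summaries.

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline assumes:
many sentences mention a theme, few describe a valid change. Sentences
are built from templates whose every phrase is covered by the fixture
lexicon and rule files; ground-truth labels, expected scores and expected
cancellation stages are computed constructively from the templates at
generation time, never by running the pipeline — circular validation is
structurally impossible. Corruptions (negation, hypothetical framing,
non-patient experiencer, history reference, missing change cue) are
injected at configurable rates; multi-theme sentences join per-theme
clauses with `;`, whose terminator/delimiter status isolates their scopes,
and comparative-cue clauses are placed first so each theme's nearest
change cue stays within its own clause. Stock repeated status lines
simulate the day-to-day repetition of real notes.

Defaults: 20 patients, 5–15 notes per patient, 3–10 sentences per note,
`p_theme` = 0.08 per theme per sentence, `p_change_given_theme` = 0.10,
corruption probabilities 0.05 each, `polarity_mix` = 0.5, repetition 0.15.
With these rates about one theme sentence in twelve ends up scored,
matching the sparsity of change sentences relative to theme sentences
observed in inpatient psychiatric notes. What the generator does **not**
emulate: real lexical variety, spelling errors, Dutch morphology,
abbreviations, cross-sentence discourse; a perfect score on synthetic
corpora therefore demonstrates internal consistency of the machinery, not
clinical-grade accuracy on real notes.

## Structured sources

Structured admission fields are encoded as three-level change categories
(worsened / unchanged / improved) by comparing start and end values under
a per-source declared ordering ("larger is worse" for prescription
counts; explicit severity rankings for ordinal fields). The shipped
orderings for juridical status and dismissal destination are assumptions,
declared in `DEFAULT_ORDERINGS` and overridable. `merge_outcomes`
assembles one row per patient with theme means and categorical columns
ordered with *worsened* first, the natural reference level for downstream
regression contrasts. Fitting such regressions is standard statistics and
out of scope here.

## Test problem sizes and numerics

Sentence scores are integers; summary means are exact rationals; the only
floating-point quantities are the evaluation ratios. The test suite runs
the end-to-end recovery check on a ~10,500-sentence corpus (170 patients,
seed fixed), the brute-force oracle equivalence on 200 random corpora of
up to 50 sentences, and the metric oracle on 1,000 random confusion
matrices; these sizes give tight behavioural coverage while keeping the
suite fast.

## Known limitations

- Trigger scopes are surface windows, not syntactic scopes; long-distance
  negation ("there is no evidence that … improved") can escape a window.
- The rule-based annotator's POS heuristics are built for the fixture
  vocabulary and template grammar; on open text its tags are rough, and
  the dependency-path variant of the linkage check only activates with an
  injected parsing backend.
- One change cue may license several themes in the same sentence; whether
  that is always clinically right is undecided, and the pairing rule is
  the place to change it.
- Phrase lists fully determine recall: unlisted conjugations or
  misspellings are invisible (mitigate with `expand_variants` and
  lemma-mode entries).
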