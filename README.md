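# clinchange

Rule-based extraction and sentiment scoring of *moments of change* in
psychiatric clinical notes.

Daily doctors' and nurses' notes repeat a patient's status over and over;
the informative sentences are the ones that describe a **change** in the
patient's state. `clinchange` finds those sentences on four
transdiagnostic outcome themes — **symptom reduction**, **social
functioning**, **general well-being** and **patient experience** — and
turns them into signed per-sentence scores and per-patient (or
per-admission-trajectory) summary means. It is aimed at clinical-NLP
researchers who want outcome variables mined from electronic health
records without diagnosis-specific questionnaires.

Everything is driven by plain-text phrase lexicons and context-rule files,
so the pipeline is language- and corpus-agnostic: swap in your own lists
(the shipped English fixture set and Dutch starter rules show the format)
and the same machinery applies.

## The pipeline

Five deterministic stages per note:

1. **Sentence split + annotation** — sentences are the unit of analysis;
   tokens carry lemma, POS, morphological degree and dependency fields.
   The annotation backend is pluggable; a deterministic rule-based
   annotator ships as the default.
2. **Theme filter** — a sentence survives only if it contains a lexicon
   phrase for some theme. Each theme phrase *t* carries a connotation
   polarity `pol(t) ∈ {−1, +1}` (e.g. *anxiety* → −1, *participation* → +1).
3. **Change filter** — the sentence must also contain a change cue: a
   change word with direction `dir(c) ∈ {−1, +1}` (*improvement* +1,
   *less* −1) or a comparative adjective form (*angrier*, always +1).
   Otherwise analysis of the sentence is cancelled.
4. **Context filter** — each (theme phrase, nearest change cue) pair must
   pass five checks: current, not hypothetical, concerns the patient, not
   negated, and the change must grammatically concern the theme. The
   first four use trigger/scope rules in the ConText style, read from a
   per-language TSV; the fifth uses dependency-path distance (or a
   token-window fallback).
5. **Scoring** — each accepted pair contributes `pol(t) × dir(c)`;
   per-sentence theme scores add the pair products, so
   *"more anxiety"* → −1, *"participation improved"* → +1, and
   *"The patient was more anxious and sad"* → (−1·+1) + (−1·+1) = −2.

Per patient or trajectory, the summary for a theme is the exact rational
mean over scored sentences (scores {−2, 1, 2} → mean 1/3); a group with no
scored sentence has an *undefined* mean, never 0.

The package also includes an evaluation harness (accept/reject sentence
annotations → per-theme accuracy/precision/recall/F1), a synthetic corpus
generator with constructive ground truth for testing every stage, and a
three-level encoder (worsened / unchanged / improved) for structured
admission data such as benzodiazepine prescription counts.

## Worked example

```bash
clinchange generate --config config.json --out corpus --seed 42   # {"n_patients": 4}
clinchange run --notes corpus/notes.jsonl --lexicon lexicon.tsv \
    --rules rules.tsv --out out
```

prints the per-theme stage trace of the 247-sentence synthetic corpus:

```
experience: sentences=247 theme_pass=21 change_pass=2 accepted=2
social: sentences=247 theme_pass=14 change_pass=2 accepted=2
symptoms: sentences=247 theme_pass=14 change_pass=0 accepted=0
wellbeing: sentences=247 theme_pass=22 change_pass=2 accepted=1
```

Read: of 247 sentences, 21 mention a patient-experience phrase but only 2
also contain a change cue in a valid context and are scored — the sparsity
that motivates change detection in the first place. `out/summaries.csv`
holds the aggregated means, e.g.

```
key_kind,key_id,theme,n_theme_sentences,n_change_sentences,mean_sentiment
trajectory,p000-T1,experience,2,0,
trajectory,p000-T1,social,4,1,1
```

(empty `mean_sentiment` = no scored sentence, mean undefined). Evaluating
the pipeline against the generator's own labels closes the loop:

```bash
clinchange evaluate --labels corpus/labels.jsonl --lexicon lexicon.tsv \
    --rules rules.tsv --out report.csv
# experience: n=247 accuracy=1.000 precision=1.000 recall=1.000 f1=1.000
# ...
```

With a matched lexicon and rule set the pipeline recovers the constructive
ground truth exactly; degrading the lexicon lowers recall but never
precision (see `tests/test_acceptance.py`).

## Layout

- `src/clinchange/lexicon.py` — phrase inventories, loading/validation, matching
- `src/clinchange/preprocess.py` — sentence splitting, rule-based annotator
- `src/clinchange/filters.py` — theme/change filters, candidate pairing
- `src/clinchange/context.py` — the five-check context filter
- `src/clinchange/scoring.py` — sentence scores, aggregation, `run_pipeline`
- `src/clinchange/evaluation.py` — accept/reject validation harness
- `src/clinchange/synthetic.py` — corpus generator with constructive truth
- `src/clinchange/structured.py` — structured-source change encoding
- `docs/methods.md` — model, parameters, design choices, limitations
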