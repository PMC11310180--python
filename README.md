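# nodule-ie

Information extraction of **pulmonary nodules and their characteristics**
from free-text radiology reports.

Lung-cancer-screening CT reports describe findings — "A 4 mm solid nodule in
the left lower lobe." — that downstream applications (Lung-RADS scoring,
surveillance-adherence studies, cohort building) need as structured data.
`nodule-ie` is a trainable NLP system that turns report text into standoff
annotations in three stages plus pre/post-processing:

1. **Concept extraction** — sequence labeling over seven concept categories
   (`Nodule`, `Site`, `Laterality`, `Size`, `Course`, `Texture`, `Shape`)
   using the BIO scheme (`B-c` first token of a concept, `I-c` inside, `O`
   outside, with an auxiliary `X` tag for non-leading sub-word pieces).
   Backends: a linear-chain **CRF** (Viterbi-decoded, so outputs are always
   transition-legal) and a sub-token window classifier.
2. **Relation identification** — a two-stage procedure links each
   characteristic to its nodule. Candidate pairs are (nodule,
   characteristic) pairs whose *cross-distance* (number of sentence
   boundaries between the entities) is below 3, a cap that covers ~96–97 %
   of gold relations while bounding the negative count. A binary classifier
   (linear SVM with fivefold-CV selection of C and tolerance, or a unified
   all-distances MLP) judges *has-relation* vs *no-relation*; the relation
   type is then assigned by rule, since exactly one type exists per
   characteristic category (`Site` → `nodule-site`, …).
3. **Negation detection** — each nodule mention is classified
   negated / non-negated from its containing sentence only ("No pulmonary
   nodule."), with the target mention delimited by marker tokens.

Postprocessing merges the three outputs per document id, canonicalizes
identifiers, and writes **BRAT standoff** (`.txt` + `.ann`), the system's
interchange format for both gold and predicted annotations.

Evaluation is **strict micro-averaged** precision/recall/F1: a concept
counts only when both character boundaries and the category match gold
exactly; a relation only when its type and both endpoint spans match; a
document-level bootstrap (20 replicates) estimates standard deviations.
Formally, with pooled counts over categories,
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), all 0/0 := 0.

Because real screening corpora are protected health information, the
package includes a **seeded synthetic-report generator**: a template
grammar over Lung-RADS-style descriptor vocabulary that emits reports with
exact gold offsets, realistic category frequencies, ~29 % negated nodule
mentions, ≥96 % of relations within cross-distance 3, and annotation-free
guideline boilerplate as distractor text. Every stage is trainable and
testable end-to-end with no external data.

## Worked example

```python
from nodule_ie import (
    GeneratorConfig, NerConfig, generate_corpus, split_documents,
    train_ner, train_pair_classifier, train_negation_classifier,
    run_pipeline, evaluate_entities, write_brat,
)

docs, splits = generate_corpus(GeneratorConfig(n_docs=433, seed=13))
train, val, test = split_documents(docs, splits)

ner = train_ner(train, val, NerConfig(backend="crf", seed=13))
rel = train_pair_classifier(train, backend="margin", seed=13)
neg = train_negation_classifier(train, seed=13)

result = run_pipeline([("report", "nodule located at the lower lobe")], ner, rel, neg)
print(write_brat(result.documents[0]))
```

prints the standoff annotation the pipeline recovered:

```
T1	Nodule 0 6	nodule
T2	Site 22 32	lower lobe
R1	nodule-site Arg1:T1 Arg2:T2
```

i.e. a nodule mention at characters 0–6, a site characteristic at 22–32,
and the `nodule-site` relation linking them. Running the same pipeline on
`"No pulmonary nodule."` adds an `A1	Negation T1` attribute line marking
the mention as negated.

The same objects drive the CLI:

```bash
nodule-ie synth --n-docs 433 --seed 13 --out corpus/
nodule-ie train ner      --corpus corpus/ --model-dir models/ner
nodule-ie train relation --corpus corpus/ --model-dir models/rel
nodule-ie train negation --corpus corpus/ --model-dir models/neg
nodule-ie run --ner-model models/ner --relation-model models/rel \
              --negation-model models/neg --in corpus/ --out pred/
nodule-ie evaluate --gold corpus/ --pred pred/ --task end2end --bootstrap 20
```

## Scope

The package extracts and links mentions; it does **not** normalize
characteristic values (units, descriptor variants), derive Lung-RADS
scores, or ship pretrained transformer checkpoints — the neural components
here are compact models trained from scratch on the synthetic corpus. See
`docs/methods.md` for the modeling details and limitations.
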