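# Methods

This note documents the models, the synthetic data they are exercised on,
and the design choices made where the design was genuinely open.

## Task and data model

A report is a `Document`: UTF-8 text (newlines normalized to `\n` before any
offset is computed, so offsets are platform-stable) plus entities,
relations, and negation flags. Entities are contiguous, 0-based,
end-exclusive character spans in one of seven categories: the nodule
mention itself and six characteristics radiologists record for Lung-RADS
assessment — anatomic site, laterality, size, interval course,
texture/density, and shape. Relations are directed nodule → characteristic
links; because the schema defines exactly one relation type per
characteristic category, relation *typing* is a bijection and only relation
*existence* needs to be learned. Negation is a binary attribute of nodule
mentions only; absence of the attribute means non-negated.

BRAT standoff is the interchange format. The dialect is deliberately
narrow: `T`/`R`/`A` lines only, single-span entities (the parser rejects
discontinuous `;` fragments), and `A# Negation T#` for negation. Event,
normalization, and note lines are skipped with a warning rather than
rejected, so corpora annotated with richer schemas still load.

## Preprocessing

Reports are not standard prose, and the relation stage's cross-distance
depends directly on sentence boundaries, so both tokenizer and sentence
splitter are fixed deterministic rule sets rather than learned models:

- **Tokens**: maximal letter runs; digit runs with an internal decimal
  point (`1.2` is one token, `4mm` splits into `4` + `mm`); any other
  non-whitespace character is its own token. Offsets always index the
  original text.
- **Sentences**: a boundary after `.`, `!`, `?`, and at any newline between
  tokens (which also terminates `FINDINGS:`-style headers).

BIO conversion is total in both directions. Decoding applies CoNLL-style
repair first — an orphan `I-c` is promoted to `B-c`, anything outside the
alphabet (including a stray `X`) becomes `O` — so *any* label sequence
decodes without error. Encoding resolves overlapping gold spans by keeping
the longer one (ties: earlier start) and splits tokens at entity boundaries
rather than snapping entity offsets, because snapping would corrupt
strict-boundary evaluation. The sub-token layer (`expand_subtokens` /
`collapse_subtokens`) moves word-level tags to sub-word level and back:
non-leading pieces get `X`, word labels are read off leading pieces, and
`collapse ∘ expand` is the identity.

## Concept extraction

Two backends satisfy one contract (per-sentence token input, BIO output):

- **`crf`** — a linear-chain CRF over sparse lexical features (lowercased
  word, word shape, 2/3-character affixes, neighbor words, adjacent-word
  conjunctions, a numeric flag). Training maximizes the penalized
  log-likelihood with L-BFGS (L2 weight 0.1, full-batch, iteration budget
  4× the epoch setting); the objective is convex, so the fit is
  deterministic and the configured seed has no effect on it. Decoding is
  Viterbi, verified in the tests against exhaustive path enumeration.
  Out-of-vocabulary words at prediction time simply activate no lexical
  features and are scored by their shape/affix/context features.
- **`subtoken`** — a per-sub-token multinomial logistic regression. Words
  are split by a fixed rule (a 4-character head piece plus 3-character
  `##`-continuations) mimicking fixed-vocabulary sub-word tokenizers;
  `X` positions are masked out of the training loss, predictions are
  collapsed to word level and passed through BIO repair.

`NerConfig` carries the historical training protocol for this task
(30 epochs, batch 4, learning rate 1e-5, seed 13, 8:2 train/validation
split by document). The batch-size and learning-rate fields are accepted
but ignored by these convex/quasi-Newton trainers; they exist so configs
remain interchangeable with SGD-style backends. Validation strict F1 is
computed and stored with every trained model.

## Relation identification

Candidates are exactly the (nodule, characteristic) pairs with
cross-distance < 3; all generated non-gold candidates serve as negatives
(the cap already bounds their number, which is the point of the
heuristic). Features per pair: entity-token unigrams and 2/3-gram
conjunctions; 2–5-gram context windows of up to 10 tokens on each side of
each entity (the n-gram orders are fixed, the window width is our choice);
the bucketed count of tokens strictly between the spans (our convention
for "token distance"); the tail category; the cross-distance; the linear
order of the pair; and the concept-tag histogram of the covered sentences,
including a bucketed count of *other nodule mentions between the pair* —
derivable from the tags and decisive in multi-nodule passages.

Backends: `margin` (LinearSVC; fivefold seeded CV over
C ∈ {0.01, 0.1, 1, 10} and tol ∈ {1e-4, 1e-3}) and `neural` (a one-hidden-
layer MLP acting as the unified all-distances classifier; fivefold CV over
the epoch budget {60, 120} and batch size {32}). The neural grid is larger
than the 3–6-epoch fine-tuning range customary for pretrained encoders
because a from-scratch network needs more passes to converge; the CV
protocol itself is unchanged. Gold relations at cross-distance ≥ 3 (the
~3–4 % tail) are unreachable by construction; the evaluator reports them
as false negatives, which is the quantified cost of the candidate cap.

One characteristic may link to several nodules: each candidate is judged
independently, with no mutual-exclusion constraint.

## Negation detection

Each nodule mention is classified from its containing sentence only; a
config window can add neighboring sentences but defaults to 0, since the
highly conventionalized negation patterns of radiology reports are local.
The mention is delimited with `[NOD] … [/NOD]` markers (a sentence can
contain several nodules), the sentence is vectorized as uni/bigram counts,
and a logistic regression (fivefold CV over C) produces softmax
probabilities; argmax at 0.5 decides. A trigger-word rule backend
(`no`, `without`, `negative`, …) is provided for dependency-free smoke
tests; it is transparent but not part of the trained protocol. Relations
whose nodule is negated are retained by default
(`PipelineConfig.drop_relations_of_negated` suppresses them).

## Pipeline and postprocessing

The merge is: BIO → entities, attach relations whose endpoints survived
decoding (dangling ones are dropped with a warning), attach negation flags
to nodule entities, then canonicalize identifiers (`T1..Tn` by start
offset, `R1..Rm` by head/tail offset) so outputs are byte-stable and
diffable. A document that fails any stage is skipped and counted, never
aborting the batch. Every emitted document must pass schema validation
and re-parse to an equal document.

## Evaluation

Strict micro-averaged P/R/F1 with per-category breakdown; duplicate
predictions of the same (span, category) are deduplicated before scoring
so a doubled prediction neither helps nor hurts twice. Relation scoring is
identical in component mode (predictions on gold entities) and end-to-end
mode (predictions on extracted entities) — only the inputs differ, and
both modes are exposed because either convention is defensible. The single
end-to-end figure pools entity, relation, and negated-flag items into one
micro average, so errors in any stage propagate; per-task end-to-end
scores are bounded by their component counterparts (tested). The bootstrap
resamples *documents* with replacement (annotations travel with their
document), 20 replicates by default, sample SD with ddof = 1.

## Synthetic corpus

The generator is a template grammar, not a language model: exact gold
offsets, full determinism from (config, seed), no downloads. Defaults
encode the statistical shape of an annotated screening corpus:

- category weights 426 : 252 : 240 : 221 : 135 : 111 : 27
  (Nodule : Site : Laterality : Size : Course : Texture : Shape), realized
  by per-nodule characteristic probabilities scaled so expected gold counts
  match the weights given that negated mentions carry no characteristics;
- negated fraction 116/404 ≈ 0.287 of nodule mentions;
- characteristic placement at cross-distance 0/1/2/≥3 with probabilities
  0.80/0.11/0.06/0.03 (≥ 96 % below 3 — the ≥3 tail exists precisely so the
  candidate cap's cost is measurable);
- 273 : 31 : 90 train/validation/test document ratios;
- guideline boilerplate ("Lung nodule follow up algorithm …") in ~30 % of
  documents, carrying **no** gold annotations, as a hard distractor that
  models must learn to ignore.

What it does **not** emulate: dictation/OCR noise, misspellings,
de-identification artifacts, template drift across institutions, and the
long-tail lexical variety of real reports. Scores on this corpus therefore
demonstrate that the machinery is correct and learnable — near-ceiling
performance is expected by construction — not that real-corpus accuracy
would match; on real data the relative ordering of stages (negation
easiest, end-to-end lowest) is the transferable observation.

## Problem sizes and numerics

Tests and the acceptance script train on a 433-document corpus (300
training documents after the split), which the package treats as its
study scale; the CRF converges in well under a minute on one CPU.
Tolerances: probability normalization 1e-6; all metric comparisons exact
or with explicit slack in the tests. Degenerate inputs are defined, not
errors: empty text yields empty token/sentence lists, a document with no
nodules yields no candidates, a corpus with no negated mentions scores
0/0 → 0 with a warning.

## Known limitations

- No characteristic-value normalization (sizes stay as text spans).
- Entities are single contiguous spans; discontinuous or nested gold is
  out of schema (overlaps are resolved, not represented).
- The sub-token backend's fixed splitting rule is a stand-in for learned
  sub-word vocabularies; it exercises the X-tag contract, not BPE.
- Hyperparameter search is limited to the small CV grids above by design.
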