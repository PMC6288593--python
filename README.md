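# adex — adverse-drug-event entity and relation extraction

`adex` is a research package for **pharmacovigilance NLP**: extracting
adverse drug events (ADEs) and the information around them — medications,
dosages, routes, frequencies, durations, indications, severities and other
signs/symptoms (SSLIF) — from free-text clinical notes.  Extraction is the
classic two-step pipeline:

1. **Named entity recognition (NER).**  A BiLSTM-CRF tagger labels each
   token with one of 37 BMES-with-type labels (`B_t/M_t/E_t/S_t` for each
   of the 9 entity types, plus `O`).  Token features are the word
   embedding, an initial-capital flag, a POS-tag embedding and a
   character-CNN vector.  The linear-chain CRF scores a labeling *y* of a
   sentence *x* as

   ```
   s(x, y) = Σ_t  E[t, y_t]  +  Σ_t  T[y_{t-1}, y_t]     (incl. START/STOP)
   p(y|x)  = exp s(x, y) / Σ_{y'} exp s(x, y')
   ```

   trained by minimizing −log p(y*|x) (forward algorithm for the partition
   sum) and decoded with Viterbi.

2. **Relation extraction (RE).**  Every ordered, type-compatible entity
   pair within a configurable sentence gap becomes a candidate — including
   inter-sentence pairs.  The candidate's token window is encoded by a
   BiLSTM over word, POS and two position embeddings (signed distances to
   each target entity); additive attention pools the hidden states into a
   context vector *c* = Σ_t α_t h_t with α = softmax(vᵀ tanh(W h)).
   Entity-pair side features (entity words, entity types, bucketed token
   distance and entities-between count) are concatenated with *c* before
   an 8-way softmax (7 relation types + None).

Because NER and RE are related tasks, the package also implements three
**multi-task couplings** and a factory to train any of them:

| mode       | coupling                                                        |
|------------|-----------------------------------------------------------------|
| `pipeline` | none (independent training, shared schedule)                     |
| `hard`     | a shared BiLSTM updated by both task losses (hard sharing)       |
| `reg`      | L2 penalty λ·Σ(θ₂ⁿᵉʳ − θ₂ʳᵉ)² tying the second BiLSTM layers     |
| `learn`    | learned linear exchange maps feeding each decoder a summary of the other task's encoder |

Evaluation is micro-averaged precision/recall/F1 with exact span matching,
reported for entities, for relations over gold entities, and **end-to-end**
(predicted entities feed the relation stage, so tagging errors propagate).

Real ADE-annotated clinical corpora are access-restricted, so the package
ships a seeded **synthetic corpus generator** that emulates their schema
and difficulty: the same 9 entity / 7 relation types, a ≈10:1 SSLIF:ADE
class imbalance, inter-sentence relations, and lexical-confound
distractors.  All models are implemented in pure numpy (a small
reverse-mode autodiff core lives in `adex._autograd`), so the package has
no deep-learning-framework dependency and runs on one CPU.

## Worked example

`examples/03_end_to_end_extraction.py` trains the pipeline on 80 synthetic
notes and scores 20 held-out notes:

```
--- predictions on one held-out note -------------------------
  Dosage-Medication      '10 mg' -> 'lanoxipram'
  Route-Medication       'orally' -> 'lanoxipram'
  Frequency-Medication   'daily' -> 'lanoxipram'
  Medication-Indication  'lanoxipram' -> 'atrial fibrillation'
  ...
--- held-out micro scores -------------------------------------
NER            F1 = 98.7
RE (gold ents) F1 = 98.9
RE (end-to-end) F1 = 95.2
```

Each prediction line is a typed relation between two extracted spans.  The
three scores are micro-averaged F1 percentages; the end-to-end relation
score is below the gold-entity score because every relation touching a
mistagged span counts as an error.  The other example scripts cover corpus
generation (`01`), the tagger alone (`02`) and a four-mode multi-task
comparison (`04`).

The same workflow is available from the shell:

```bash
adex generate --out corpus --seed 13
adex train --corpus corpus/train --mode hard --out model --seed 13
adex predict --model model --input corpus/test --out pred
adex evaluate --gold corpus/test --pred pred
adex run-all --workdir run1 --mode all --seed 13   # everything at once
```

## Layout

```
src/adex/
  corpus.py         # 9-entity / 7-relation schema, BRAT-style standoff I/O
  preprocessing.py  # tokenizer, rule POS tagger, BMES codec, candidates
  _autograd.py      # minimal reverse-mode autodiff on numpy
  nn.py             # embeddings, BiLSTM, char-CNN, attention pieces, Adam
  ner.py            # BiLSTM-CRF tagger
  relation.py       # BiLSTM-attention relation classifier
  mtl.py            # pipeline / hard / reg / learn couplings + trainer
  evaluation.py     # micro-averaged exact-match scoring
  synthetic.py      # seeded schema-faithful corpus generator
  cli.py            # generate / train / predict / evaluate / run-all
docs/methods.md     # modeling choices, parameters, limitations
```
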