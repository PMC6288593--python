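# Methods

## Task and data model

The package extracts drug-safety information from clinical narrative in
two steps: sequence labeling of entity mentions, then classification of
ordered entity pairs into typed relations.  The annotation schema is
closed: 9 entity types (Medication, Indication, Frequency, Severity,
Dosage, Duration, Route, ADE, SSLIF) and 7 relation types, each of which
fixes the entity types of its two arguments (e.g. `Severity-ADE` links a
Severity to an ADE).  Documents are stored as BRAT-style standoff —
UTF-8 text plus tab-separated annotation lines with 0-based half-open
character offsets.  The on-disk dialect is a design choice of this
package: line-oriented, diffable and exactly invertible, which the tests
exploit (write∘read is asserted to be the identity on every generated
corpus).

Discontiguous and overlapping entity spans are out of scope.  Entity
spans that do not sit on token boundaries are snapped outward to the
smallest covering token span, with each snap reported to the caller;
real clinical tokenization is imperfect and silent truncation would bias
evaluation.

## Entity tagger

Spans are encoded per sentence with the BMES scheme plus type: a
multi-token entity becomes `B_t … E_t` with `M_t` in between, a
single-token entity `S_t`, everything else `O` — 37 labels in all.
Decoding must handle ill-formed model output; the repair rule is
*strict-left*: an `M`/`E` with no live same-type `B` run to its left is
treated as `O`, and a `B` run that never reaches its `E` is truncated at
the last contiguous same-type `M` (a lone `B` yields a single-token
entity).  The rule is deterministic and is verified in the tests against
an independent regex formulation (`S | B M* E | B M*`) on every label
pattern up to length 4.

Token features: word embedding (lowercased vocabulary, unknown → UNK),
initial-capital flag embedding, POS-tag embedding, and a character CNN
(embed characters, convolve with width-3 filters, tanh, max-pool) that
captures morphology such as drug-name suffixes.  The POS tagger bundled
by default is a deterministic rule system (closed-class lexicon plus
suffix heuristics over a Penn-style tagset); it exists so the package
needs no model download and is pluggable — any callable that fills
`Token.pos` can replace it.

The concatenated features pass through one (configurably more)
bidirectional LSTM layer and a linear projection to per-token emission
scores.  A linear-chain CRF with learned transition scores (including
virtual START/STOP) supplies the loss — mean over sentences of
log-partition minus gold-path score, computed with the forward recursion
in log space — and Viterbi decoding.  Transitions into structurally
impossible BMES successors are *learned*, not masked, by default; a
config flag (`constrain_decode`) adds a hard mask at decode time.  Both
behaviors are testable; learned transitions are the default because the
model reliably learns them and masking can hide calibration problems.
Viterbi ties break toward the lowest label index, making decoding fully
deterministic.

## Relation classifier

Candidates are all ordered entity pairs whose types match one of the 7
signatures and whose sentence distance is at most `max_sentence_gap`
(default 3).  Argument order is canonical — the signature fixes which
entity is arg1 — so each compatible pair yields exactly one candidate.
The context window runs from the first token of the earlier entity's
sentence to the last token of the later entity's sentence, so
inter-sentence pairs see the full intervening text.  Per-token features
are word, POS and two position embeddings — the signed token distance to
each target entity (negative before, 0 inside, positive after), clipped
at ±`max_position` (default 20).  Character features are deliberately
absent from this stage; they did not help relation classification in the
work this package follows.

A BiLSTM encodes the window; single-query additive attention
(α = softmax(vᵀ tanh(W h))) pools it into a context vector.  Side
features — mean word embedding of each entity mention, both entity-type
embeddings, and bucketed token-distance and entities-between counts
(buckets {0, 1, 2, 3–5, 6–10, >10}) — are embedded rather than fed as raw
scalars and concatenated with the context vector before the 8-way softmax
(7 types + None).  Argmax ties resolve to None: extraction should be
conservative.  At extraction time a pair is emitted only when the
predicted class equals the single relation its entity types admit, which
makes schema validity of the output a construction invariant rather than
a hope.  Negative ("None") candidates can be down-sampled during training
by `negative_keep`; the default keeps all of them.

## Multi-task couplings

All four regimes share one trainer: per step, one tagger batch and one
relation batch (the shorter loader cycles), one joint loss, one Adam step.

* **pipeline** — no interaction; since each loss touches only its own
  parameters, the trajectory equals independent training under the same
  seeds.
* **hard** — a shared BiLSTM reads each task's word+POS embeddings (the
  dimensions must agree) and its output is concatenated with the private
  encoder's before the task decoder.  Concatenation rather than summation
  preserves both signals and makes the shape contract checkable.  The
  shared input is the word+POS subset of each task's features because the
  full feature vectors have task-specific widths.
* **reg** — both tasks use two stacked BiLSTM layers; the first layers
  have task-specific input widths and stay free, the second layers are
  shape-identical and coupled by λ·Σ(θ₂ⁿᵉʳ − θ₂ʳᵉ)² added to the joint
  loss (λ default 1e-3).  With λ = 0 the penalty is skipped entirely, so
  the reg system reproduces the pipeline bit for bit under equal seeds —
  a contract the tests assert.
* **learn** — two direction-specific linear exchange maps (bias-free, so
  a zero map contributes exactly zeros): the relation encoder's attention
  context, mapped into the tagger's decoder and broadcast over tokens;
  and a mean-pooled tagger encoding of the candidate window, mapped into
  the relation output layer.  For a plain sentence with no target
  entities the counterpart relation encoder runs with both distances
  fixed at zero.  Direction-specific maps were chosen over a single tied
  map because the two hidden spaces have no reason to share a basis.

No claim is made about which coupling wins: on the synthetic corpus all
modes saturate, and on real data the ranking is known to be
data-dependent.

## Synthetic corpus

The generator emulates the statistical shape of ADE-annotated notes with
a closed invented vocabulary (no real patient text, no drug database):
template frames for medication starts ("Patient started <Medication>
<Dosage> <Route> <Frequency> for <Indication>"), durations, ADE onsets,
symptom listings, neutral filler, and — scheduled by `noise_rate` — two
confounds mirroring real error sources: SSLIF mentions whose surface form
is drawn from the ADE lexicon, and a "held given <Indication>" frame that
places relation-free entity pairs in relation-suggestive contexts.  The
relational ground truth is a closed rule set (attributes modify their
template's medication; an ADE attaches to the closest preceding in-window
medication), so the patterns are learnable by construction.

Per-document template counts use floor-plus-stochastic-rounding
allocation, which keeps the realized class imbalance close to the
configured ≈10:1 SSLIF:ADE ratio at a couple hundred documents while
staying unbiased for categories rarer than one sentence per note.
`intersentence_fraction` (default 0.15) schedules ADE frames that refer
back to a medication up to `max_relation_gap` (default 2) sentences
earlier; the realized inter-sentence share is lower than the knob because
the back-reference also requires a recent medication mention.

What passing tests on this corpus do and do not show: they demonstrate
that the full stack — features, CRF, attention, couplings, decoding,
scoring — is implemented correctly and can learn compositional span and
relation patterns end to end.  They do not demonstrate clinical-grade
accuracy: real notes have vastly larger vocabularies, misspellings,
section structure, genuinely ambiguous ADE/Indication/SSLIF distinctions
and longer-range discourse, none of which the templates reproduce.
Near-ceiling synthetic scores are a correctness check, not a performance
claim.

## Numerical and scale choices

Everything runs in float64 on numpy via a small reverse-mode autodiff
core; gradients of every primitive are finite-difference-tested.  The
log-partition and attention softmax are computed with max-shifted
log-sum-exp.  Padding is explicit: batches are right-padded, masks gate
the LSTM state so padded steps are identities, attention masks padding to
−1e9 before the softmax, and the CRF sums only over real tokens.  Adam
(lr 2e-3) with global gradient-norm clipping at 5 is the optimizer
throughout.

Default sizes — word 48, char 16→24 filters width 3, POS 10, capital 4,
LSTM 48 per direction, dropout 0.2, batch 32, 5 epochs — are deliberately
compact: they saturate the synthetic benchmark in a few minutes on a
single CPU core, and every dimension is config-exposed for larger runs.
Pretrained word embeddings in plain word2vec text format can be loaded
and are frozen by default (tuning them tends to overfit small corpora).
The default experiment scale is 200 training / 50 test documents.

One integer seed per component controls initialization, shuffling and
dropout; identical configs and seeds reproduce losses, parameters and
reports bit for bit, which the reproducibility tests assert.

## Limitations

* Exact-span matching only; no partial-credit or overlap scoring modes.
* No coreference, no dependency structure, no document-level relation
  aggregation beyond pairwise classification.
* Relations spanning more sentences than `max_sentence_gap` are
  unreachable by construction — the knob trades recall for candidate
  count.
* The rule POS tagger is crude outside the synthetic vocabulary; plug in
  a trained tagger for real notes.
* The numpy backend favors transparency over speed; large-corpus training
  would want a compiled framework behind the same module surfaces.
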