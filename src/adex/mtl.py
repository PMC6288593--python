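"""Couplings between the entity tagger and the relation classifier.

Four training regimes share one alternating mini-batch trainer (one tagger
batch and one relation batch per step, cycling the shorter loader, one
optimizer step over the joint loss):

* ``pipeline`` — no coupling; the two submodels merely share the schedule,
  which makes their parameter trajectories identical to independent
  training (each loss touches only its own parameters).
* ``hard`` — hard parameter sharing: besides its private recurrent
  encoder, each task runs a shared bidirectional LSTM over its word+POS
  embeddings; private and shared outputs are concatenated before the
  task decoder, so the shared weights receive gradients from both losses.
* ``reg`` — soft sharing by L2 regularization: each task keeps two stacked
  recurrent layers; the first layers have task-specific input widths and
  stay free, while the (shape-identical) second layers are pulled together
  by a penalty λ·Σ(θ₂ⁿᵉʳ − θ₂ʳᵉ)² added to the joint loss.
* ``learn`` — task-relation learning: a linear exchange map per direction
  carries a pooled summary of the counterpart encoder into each decoder,
  which consumes [own hidden ∥ exchanged vector].  During tagging the
  counterpart runs on the same sentence (with zero entity distances);
  during relation classification it runs on the candidate window.
"""

from __future__ import annotations

import json
import os
from dataclasses import replace

import numpy as np

from ._autograd import Parameter, Tensor, concat
from .corpus import Document, with_annotations
from .evaluation import evaluate_documents
from .ner import NerConfig, NerModel, prepare_ner_data
from .nn import Adam, BiLSTM, Linear, Module, cross_entropy, dropout
from .preprocessing import Vocab
from .relation import (ReConfig, ReModel, extract_relations, attention_pool,
                       prepare_re_data)

__all__ = [
    "MODES", "ExtractionSystem", "HardMTL", "RegMTL", "LearnMTL",
    "regmtl_penalty", "train_multitask", "evaluate_system",
]

MODES = ("pipeline", "hard", "reg", "learn")


def regmtl_penalty(p2_ner: list, p2_re: list, lambda_reg: float) -> Tensor:
    """λ · Σ (θⁿᵉʳ − θʳᵉ)² over paired parameter tensors.

    Zero for tied parameters; for a unit elementwise offset over k entries
    and λ=1 the value is exactly k.  Raises on shape mismatch.
    """
    if len(p2_ner) != len(p2_re):
        raise ValueError("parameter lists differ in length")
    total = None
    for a, b in zip(p2_ner, p2_re):
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
        term = ((a - b) ** 2.0).sum()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("empty parameter lists")
    return total * lambda_reg


class ExtractionSystem(Module):
    """Pipeline (uncoupled) tagger + relation classifier.

    Subclasses override :meth:`_allocate` to install coupled encoders and
    :meth:`penalty` to contribute extra loss terms.
    """

    mode = "pipeline"

    def __init__(self, ner_config: NerConfig | None = None,
                 re_config: ReConfig | None = None):
        self.ner = NerModel(ner_config)
        self.re = ReModel(re_config)
        self.built = False

    # -------------------------------------------------------- construction
    def build(self, ner_sentences: list, re_instances: list):
        self._allocate(ner_sentences, re_instances)
        self.built = True

    def _allocate(self, ner_sentences, re_instances):
        self.ner.build(ner_sentences)
        self.re.build(re_instances)

    def trainable_parameters(self):
        skip = {id(self.ner.word_emb.weight)} if self.ner._frozen_words \
            else set()
        return [p for p in self.parameters() if id(p) not in skip]

    # -------------------------------------------------------------- losses
    def loss_ner(self, batch: dict, train: bool = False, rng=None) -> Tensor:
        return self.ner.loss_on(batch, train=train, rng=rng)

    def loss_re(self, batch: dict, train: bool = False, rng=None) -> Tensor:
        return cross_entropy(self.re.logits(batch, train=train, rng=rng),
                             batch["labels"])

    def penalty(self) -> Tensor | None:
        return None

    # ------------------------------------------------------------ training
    def fit(self, docs: list[Document], epochs: int | None = None,
            dev_docs: list[Document] | None = None,
            log: list | None = None) -> list:
        """Alternating 1:1 mini-batch training of both tasks.

        When `dev_docs` is given, per-epoch held-out micro-F1s are added
        to the log rows alongside the task losses."""
        if not docs:
            raise ValueError("empty training corpus")
        ner_data = prepare_ner_data(docs)
        re_instances = prepare_re_data(
            docs, self.re.config.max_sentence_gap,
            self.re.config.negative_keep, self.re.config.seed)
        if not re_instances:
            raise ValueError("no relation candidates in training corpus")
        self.build([s for s, _ in ner_data], re_instances)
        self.ner.trained = self.re.trained = True
        epochs = epochs if epochs is not None else self.ner.config.epochs
        ner_rng = np.random.default_rng(self.ner.config.seed + 1)
        re_rng = np.random.default_rng(self.re.config.seed + 1)
        opt = Adam(self.trainable_parameters(),
                   lr=self.ner.config.learning_rate)
        bs_n = self.ner.config.batch_size
        bs_r = self.re.config.batch_size
        log = [] if log is None else log
        for epoch in range(epochs):
            n_ord = ner_rng.permutation(len(ner_data))
            r_ord = re_rng.permutation(len(re_instances))
            nb = [n_ord[i:i + bs_n] for i in range(0, len(n_ord), bs_n)]
            rb = [r_ord[i:i + bs_r] for i in range(0, len(r_ord), bs_r)]
            steps = max(len(nb), len(rb))
            tot_n = tot_r = tot_p = 0.0
            for k in range(steps):
                idx_n = nb[k % len(nb)]
                idx_r = rb[k % len(rb)]
                batch_n = self.ner.featurize(
                    [ner_data[i][0] for i in idx_n],
                    [ner_data[i][1] for i in idx_n])
                chunk_r = [re_instances[i] for i in idx_r]
                batch_r = self.re.featurize(chunk_r)
                self.zero_grad()
                l_n = self.loss_ner(batch_n, train=True, rng=ner_rng)
                l_r = self.loss_re(batch_r, train=True, rng=re_rng)
                loss = l_n + l_r
                pen = self.penalty()
                if pen is not None:
                    loss = loss + pen
                    tot_p += pen.item()
                loss.backward()
                opt.step()
                tot_n += l_n.item()
                tot_r += l_r.item()
            row = {"mode": self.mode, "epoch": epoch,
                   "ner_loss": tot_n / steps, "re_loss": tot_r / steps,
                   "penalty": tot_p / steps}
            if dev_docs:
                rep = evaluate_system(self, dev_docs)
                row["dev_ner_f1"] = rep["ner"]["f1"]
                row["dev_re_f1"] = rep["relation_end_to_end"]["f1"]
            log.append(row)
        return log

    # ----------------------------------------------------------- inference
    def predict_document(self, doc: Document) -> Document:
        """End-to-end prediction: tagged entities feed the relation stage."""
        entities = self.ner.predict_entities(doc)
        relations = extract_relations(doc, entities, self.re)
        return with_annotations(doc, entities=entities, relations=relations)

    def predict_relations_on_gold(self, doc: Document) -> Document:
        """Relation prediction over the gold entity layer."""
        relations = extract_relations(doc, doc.entities, self.re)
        return with_annotations(doc, relations=relations)

    # -------------------------------------------------------- persistence
    def _meta_extras(self) -> dict:
        return {}

    def save(self, path: str):
        os.makedirs(path, exist_ok=True)
        from dataclasses import asdict
        meta = {"mode": self.mode,
                "ner_config": asdict(self.ner.config),
                "re_config": asdict(self.re.config),
                "ner_word_vocab": self.ner.word_vocab.to_json(),
                "ner_char_vocab": self.ner.char_vocab.to_json(),
                "ner_pos_vocab": self.ner.pos_vocab.to_json(),
                "re_word_vocab": self.re.word_vocab.to_json(),
                "re_pos_vocab": self.re.pos_vocab.to_json(),
                "trained": self.ner.trained,
                "extras": self._meta_extras()}
        with open(os.path.join(path, "system.json"), "w") as fh:
            json.dump(meta, fh)
        np.savez(os.path.join(path, "params.npz"), **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "ExtractionSystem":
        with open(os.path.join(path, "system.json")) as fh:
            meta = json.load(fh)
        ner_cfg = NerConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in meta["ner_config"].items()})
        re_cfg = ReConfig(**meta["re_config"])
        klass = {c.mode: c for c in (ExtractionSystem, HardMTL, RegMTL,
                                     LearnMTL)}[meta["mode"]]
        kwargs = meta["extras"]
        system = klass(ner_cfg, re_cfg, **kwargs)
        system.ner.word_vocab = Vocab.from_json(meta["ner_word_vocab"])
        system.ner.char_vocab = Vocab.from_json(meta["ner_char_vocab"])
        system.ner.pos_vocab = Vocab.from_json(meta["ner_pos_vocab"])
        system.re.word_vocab = Vocab.from_json(meta["re_word_vocab"])
        system.re.pos_vocab = Vocab.from_json(meta["re_pos_vocab"])
        system.build([], [])
        system.load_state_dict(dict(np.load(os.path.join(path,
                                                         "params.npz"))))
        system.ner.trained = system.re.trained = meta["trained"]
        return system


class HardMTL(ExtractionSystem):
    """Hard parameter sharing: a shared BiLSTM used by both tasks.

    The shared layer reads each task's word+POS embeddings (equal widths
    are required), so an update on either task's loss moves the shared
    weights while leaving the other task's private parameters untouched.
    """

    mode = "hard"

    def __init__(self, ner_config=None, re_config=None,
                 shared_hidden: int | None = None):
        super().__init__(ner_config, re_config)
        if self.ner.config.word_dim != self.re.config.word_dim or \
                self.ner.config.pos_dim != self.re.config.pos_dim:
            raise ValueError("hard sharing requires equal word/pos dims")
        self.shared_hidden = shared_hidden or self.ner.config.lstm_hidden

    def _meta_extras(self):
        return {"shared_hidden": self.shared_hidden}

    @property
    def lstm_share(self) -> BiLSTM:
        return self.shared_lstm

    def _allocate(self, ner_sentences, re_instances):
        sh = self.shared_hidden
        self.ner.build(ner_sentences, proj_extra=2 * sh)
        self.re.build(re_instances, hidden_extra=2 * sh)
        rng = np.random.default_rng(self.ner.config.seed + 101)
        self.shared_lstm = BiLSTM(
            self.ner.config.word_dim + self.ner.config.pos_dim, sh, rng)
        self.ner.encode_hook = self._ner_emissions
        self.re.encode_hook = self._re_hidden

    def _shared_pass(self, model, batch) -> Tensor:
        x = concat([model.word_emb(batch["word"]),
                    model.pos_emb(batch["pos"])], axis=2)
        x = x * Tensor(batch["mask"][:, :, None])
        return self.shared_lstm(x, batch["mask"])

    def _ner_emissions(self, batch, train, rng):
        h_priv = self.ner.hidden(batch, train=train, rng=rng)
        h = concat([h_priv, self._shared_pass(self.ner, batch)], axis=2)
        h = dropout(h, self.ner.config.dropout, rng, train)
        return self.ner.proj(h)

    def _re_hidden(self, batch, train, rng):
        h_priv = self.re.input_repr(batch, train=train, rng=rng)
        for lstm in self.re.lstms:
            h_priv = lstm(h_priv, batch["mask"])
        return concat([h_priv, self._shared_pass(self.re, batch)], axis=2)


class RegMTL(ExtractionSystem):
    """Soft sharing via L2 regularization of the second recurrent layers.

    The first layers have task-specific input widths and are left free;
    the second layers are shape-identical and coupled by the penalty.
    With ``lambda_reg = 0`` the loss, gradients and parameter trajectory
    are exactly those of the pipeline system under the same seeds.
    """

    mode = "reg"

    def __init__(self, ner_config=None, re_config=None,
                 lambda_reg: float = 1e-3):
        super().__init__(ner_config, re_config)
        if self.ner.config.lstm_layers < 2 or self.re.config.lstm_layers < 2:
            raise ValueError("reg coupling needs two stacked recurrent "
                             "layers per task (lstm_layers >= 2)")
        if self.ner.config.lstm_hidden != self.re.config.lstm_hidden:
            raise ValueError("second-layer shapes must match "
                             "(equal lstm_hidden)")
        if lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        self.lambda_reg = lambda_reg

    def _meta_extras(self):
        return {"lambda_reg": self.lambda_reg}

    def second_layer_params(self) -> tuple[list, list]:
        def params(layer):
            return [layer.fwd.Wx, layer.fwd.Wh, layer.fwd.b,
                    layer.bwd.Wx, layer.bwd.Wh, layer.bwd.b]
        return params(self.ner.lstms[1]), params(self.re.lstms[1])

    def penalty(self) -> Tensor | None:
        if self.lambda_reg == 0:
            return None  # vanishes identically; keep pipeline code path
        p_ner, p_re = self.second_layer_params()
        return regmtl_penalty(p_ner, p_re, self.lambda_reg)


class LearnMTL(ExtractionSystem):
    """Task-relation learning with direction-specific exchange maps.

    ``W5_re_to_ner`` maps the counterpart relation encoder's attention
    context into the tagger's decoder; ``W5_ner_to_re`` maps a mean-pooled
    tagger encoding of the candidate window into the relation output
    layer.  With both maps zero, every decoder sees its no-exchange input
    widened by zeros.
    """

    mode = "learn"

    def __init__(self, ner_config=None, re_config=None,
                 exchange_dim: int = 24):
        super().__init__(ner_config, re_config)
        if exchange_dim < 1:
            raise ValueError("exchange_dim must be positive")
        self.exchange_dim = exchange_dim

    def _meta_extras(self):
        return {"exchange_dim": self.exchange_dim}

    def _allocate(self, ner_sentences, re_instances):
        ex = self.exchange_dim
        self.ner.build(ner_sentences, proj_extra=ex)
        self.re.build(re_instances, out_extra=ex)
        rng = np.random.default_rng(self.ner.config.seed + 202)
        self.W5_re_to_ner = Linear(2 * self.re.config.lstm_hidden, ex, rng,
                                   bias=False)
        self.W5_ner_to_re = Linear(2 * self.ner.config.lstm_hidden, ex, rng,
                                   bias=False)
        self.ner.encode_hook = self._ner_emissions
        self.re.ctx_extra_hook = self._re_exchange

    # -- counterpart views -------------------------------------------------
    def _re_view(self, sentences) -> dict:
        """Featurize plain sentences for the relation encoder: no target
        entities, so both entity distances are zero everywhere."""
        B = len(sentences)
        T = max(len(s) for s in sentences)
        zero_pos = self.re.config.max_position + 1  # index of distance 0
        word = np.zeros((B, T), dtype=np.intp)
        pos = np.zeros((B, T), dtype=np.intp)
        p = np.zeros((B, T), dtype=np.intp)
        mask = np.zeros((B, T))
        for i, sent in enumerate(sentences):
            for j, tok in enumerate(sent):
                word[i, j] = self.re.word_vocab[self.re._norm(tok.text)]
                pos[i, j] = self.re.pos_vocab[tok.pos]
                p[i, j] = zero_pos
                mask[i, j] = 1.0
        return {"word": word, "pos": pos, "p1": p, "p2": p, "mask": mask}

    def _ner_emissions(self, batch, train, rng):
        h_priv = self.ner.hidden(batch, train=train, rng=rng)
        re_batch = self._re_view(batch["sents"])
        h_re = self.re.input_repr(re_batch, train=train, rng=rng)
        for lstm in self.re.lstms:
            h_re = lstm(h_re, re_batch["mask"])
        ctx, _ = attention_pool(h_re, self.re.att_W, self.re.att_v,
                                re_batch["mask"])
        ex = self.W5_re_to_ner(ctx)                       # (B, ex)
        B, T = batch["mask"].shape
        ex_tok = ex.reshape(B, 1, self.exchange_dim) \
            * Tensor(np.ones((1, T, 1)))
        h = concat([h_priv, ex_tok], axis=2)
        h = dropout(h, self.ner.config.dropout, rng, train)
        return self.ner.proj(h)

    def _re_exchange(self, batch, train, rng):
        ner_batch = self.ner.featurize(batch["sents"])
        h = self.ner.hidden(ner_batch, train=train, rng=rng)
        m = ner_batch["mask"]
        pooled = (h * Tensor(m[:, :, None])).sum(axis=1) \
            * Tensor(1.0 / m.sum(axis=1)[:, None])
        return self.W5_ner_to_re(pooled)


def train_multitask(mode: str, docs: list[Document],
                    ner_config: NerConfig | None = None,
                    re_config: ReConfig | None = None,
                    epochs: int | None = None,
                    lambda_reg: float = 1e-3,
                    shared_hidden: int | None = None,
                    exchange_dim: int = 24,
                    log: list | None = None
                    ) -> tuple[ExtractionSystem, list]:
    """Construct and train a system in the given mode; returns (system, log).

    For ``reg`` mode, configs with fewer than two recurrent layers are
    upgraded to two so the second layers exist to regularize.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    ner_config = ner_config or NerConfig()
    re_config = re_config or ReConfig()
    if mode == "pipeline":
        system = ExtractionSystem(ner_config, re_config)
    elif mode == "hard":
        system = HardMTL(ner_config, re_config, shared_hidden=shared_hidden)
    elif mode == "reg":
        if ner_config.lstm_layers < 2:
            ner_config = replace(ner_config, lstm_layers=2)
        if re_config.lstm_layers < 2:
            re_config = replace(re_config, lstm_layers=2)
        system = RegMTL(ner_config, re_config, lambda_reg=lambda_reg)
    else:
        system = LearnMTL(ner_config, re_config, exchange_dim=exchange_dim)
    out_log = system.fit(docs, epochs=epochs, log=log)
    return system, out_log


def evaluate_system(system: ExtractionSystem, docs: list[Document]) -> dict:
    """NER, relation-on-gold-entities, and end-to-end relation micro scores
    of a trained system on gold-annotated documents."""
    end2end = [system.predict_document(d) for d in docs]
    on_gold = [system.predict_relations_on_gold(d) for d in docs]
    rep_e2e = evaluate_documents(docs, end2end, end_to_end=True)
    rep_gold = evaluate_documents(docs, on_gold, end_to_end=False)
    return {"mode": system.mode,
            "ner": rep_e2e["entity"],
            "relation_gold_entities": rep_gold["relation"],
            "relation_end_to_end": rep_e2e["relation"]}
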