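"""Attention-pooled recurrent classifier for the 7 drug-event relations.

A candidate is an ordered, type-compatible entity pair with the token
window spanning both entities (possibly across sentences).  Token features
are word, part-of-speech and two position embeddings (signed token distance
to each target entity, clipped at ``max_position``); a bidirectional LSTM
encodes the window and additive attention pools it into a context vector.
No character features are used at this stage — they did not help relation
classification in the experiments this design follows.

Entity-pair side features — surface words of both entities (mean of word
embeddings for multi-word mentions), both entity types, and bucketed
token-distance / entities-between counts — are concatenated with the
context vector before the 8-way softmax (7 relation types + "None").
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from ._autograd import Parameter, Tensor, concat, softmax
from .corpus import (ENTITY_TYPES, RELATION_TYPES, Document, Entity,
                     Relation)
from .nn import Adam, BiLSTM, Embedding, Linear, Module, cross_entropy, dropout
from .preprocessing import (DISTANCE_BUCKETS, RelationInstance, Vocab,
                            bucket_distance, build_relation_candidates,
                            pos_tag, tokenize_and_split)

__all__ = ["ReConfig", "ReModel", "RELATION_CLASSES", "attention_pool",
           "extract_relations"]

#: class 0 is "None" so that argmax ties resolve to no-relation
RELATION_CLASSES: tuple[str, ...] = ("None",) + RELATION_TYPES
CLASS_TO_ID = {c: i for i, c in enumerate(RELATION_CLASSES)}
TYPE_TO_ID = {t: i + 1 for i, t in enumerate(ENTITY_TYPES)}  # 0 = pad


@dataclass
class ReConfig:
    word_dim: int = 48
    pos_dim: int = 10
    position_dim: int = 10
    max_position: int = 20
    lstm_hidden: int = 48        # per direction
    lstm_layers: int = 1
    attention_dim: int = 48
    type_dim: int = 10
    bucket_dim: int = 8
    dropout: float = 0.2
    learning_rate: float = 2e-3
    batch_size: int = 32
    epochs: int = 5
    seed: int = 0
    max_sentence_gap: int = 3
    negative_keep: float = 1.0   # down-sampling ratio for "None" instances
    lowercase: bool = True

    def validate(self):
        dims = (self.word_dim, self.pos_dim, self.position_dim,
                self.lstm_hidden, self.attention_dim, self.type_dim,
                self.bucket_dim, self.batch_size)
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if self.max_position < 1:
            raise ValueError("max_position must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.negative_keep <= 1.0:
            raise ValueError("negative_keep must be in (0, 1]")


def attention_pool(hidden: Tensor, W: Linear, v: Parameter,
                   mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """Additive attention: softmax(vᵀ tanh(W h_t)) over real tokens.

    Returns (context (B, H), weights (B, T)); weights are non-negative,
    sum to 1 per row, and are invariant to a constant shift of the scores.
    """
    scores = W(hidden).tanh() @ v.reshape(-1, 1)      # (B, T, 1)
    scores = scores.reshape(*hidden.shape[:2])        # (B, T)
    scores = scores + Tensor((1.0 - mask) * -1e9)     # mask out padding
    weights = softmax(scores, axis=1)
    context = (hidden * weights.reshape(*weights.shape, 1)).sum(axis=1)
    return context, weights


class UntrainedModelError(RuntimeError):
    pass


class ReModel(Module):
    """BiLSTM-Attention relation classifier with entity-pair side features."""

    def __init__(self, config: ReConfig | None = None):
        self.config = config or ReConfig()
        self.config.validate()
        self.rng = np.random.default_rng(self.config.seed)
        self.word_vocab = Vocab()
        self.pos_vocab = Vocab()
        self.trained = False
        self._built = False
        self.hidden_extra = 0
        self.out_extra = 0
        #: multi-task hooks: encode_hook replaces the per-token encoder,
        #: ctx_extra_hook appends a vector to the pooled context
        self.encode_hook = None
        self.ctx_extra_hook = None

    # -------------------------------------------------------- construction
    def build(self, instances: list[RelationInstance],
              hidden_extra: int = 0, out_extra: int = 0):
        """Build vocabularies and parameters.  `hidden_extra` widens the
        per-token hidden vectors seen by attention (shared-encoder
        couplings); `out_extra` widens the pooled context fed to the
        output layer (exchange couplings)."""
        cfg = self.config
        self.hidden_extra, self.out_extra = hidden_extra, out_extra
        for inst in instances:
            for tok in inst.window:
                self.word_vocab.add(self._norm(tok.text))
                self.pos_vocab.add(tok.pos)
        rng = self.rng
        n_pos_idx = 2 * cfg.max_position + 2  # clipped signed range + pad
        self.word_emb = Embedding(len(self.word_vocab), cfg.word_dim, rng)
        self.pos_emb = Embedding(len(self.pos_vocab), cfg.pos_dim, rng)
        self.pos1_emb = Embedding(n_pos_idx, cfg.position_dim, rng)
        self.pos2_emb = Embedding(n_pos_idx, cfg.position_dim, rng)
        self.type_emb = Embedding(len(ENTITY_TYPES) + 1, cfg.type_dim, rng)
        self.dist_emb = Embedding(len(DISTANCE_BUCKETS) + 1, cfg.bucket_dim,
                                  rng)
        self.count_emb = Embedding(len(DISTANCE_BUCKETS) + 1, cfg.bucket_dim,
                                   rng)
        in_dim = cfg.word_dim + cfg.pos_dim + 2 * cfg.position_dim
        self.lstms = []
        for layer in range(cfg.lstm_layers):
            self.lstms.append(BiLSTM(in_dim if layer == 0
                                     else 2 * cfg.lstm_hidden,
                                     cfg.lstm_hidden, rng))
        h_dim = 2 * cfg.lstm_hidden + hidden_extra
        self.att_W = Linear(h_dim, cfg.attention_dim, rng)
        self.att_v = Parameter(rng.normal(0, 0.1, cfg.attention_dim))
        side_dim = 2 * cfg.word_dim + 2 * cfg.type_dim + 2 * cfg.bucket_dim
        self.out = Linear(h_dim + out_extra + side_dim,
                          len(RELATION_CLASSES), rng)
        self._built = True

    def _norm(self, text: str) -> str:
        return text.lower() if self.config.lowercase else text

    # ------------------------------------------------------------ batching
    def _position_index(self, p: int) -> int:
        mp = self.config.max_position
        return int(np.clip(p, -mp, mp)) + mp + 1

    def featurize(self, instances: list[RelationInstance]) -> dict:
        cfg = self.config
        B = len(instances)
        T = max(len(inst.window) for inst in instances)
        word = np.zeros((B, T), dtype=np.intp)
        pos = np.zeros((B, T), dtype=np.intp)
        p1 = np.zeros((B, T), dtype=np.intp)
        p2 = np.zeros((B, T), dtype=np.intp)
        mask = np.zeros((B, T))
        # side features
        e1w = np.zeros((B, T), dtype=np.intp)  # padded entity-word lists
        e2w = np.zeros((B, T), dtype=np.intp)
        e1n = np.zeros(B)
        e2n = np.zeros(B)
        types = np.zeros((B, 2), dtype=np.intp)
        dist = np.zeros(B, dtype=np.intp)
        cnt = np.zeros(B, dtype=np.intp)
        labels = np.zeros(B, dtype=np.intp)
        for i, inst in enumerate(instances):
            for j, tok in enumerate(inst.window):
                word[i, j] = self.word_vocab[self._norm(tok.text)]
                pos[i, j] = self.pos_vocab[tok.pos]
                p1[i, j] = self._position_index(inst.positions1[j])
                p2[i, j] = self._position_index(inst.positions2[j])
                mask[i, j] = 1.0
            s1, s2 = inst.span1, inst.span2
            for k, j in enumerate(range(s1[0], s1[1] + 1)):
                e1w[i, k] = word[i, j]
            for k, j in enumerate(range(s2[0], s2[1] + 1)):
                e2w[i, k] = word[i, j]
            e1n[i] = s1[1] - s1[0] + 1
            e2n[i] = s2[1] - s2[0] + 1
            types[i, 0] = TYPE_TO_ID[inst.e1.etype]
            types[i, 1] = TYPE_TO_ID[inst.e2.etype]
            dist[i] = bucket_distance(inst.token_distance) + 1
            cnt[i] = bucket_distance(inst.entity_count_between) + 1
            labels[i] = CLASS_TO_ID[inst.label]
        return {"word": word, "pos": pos, "p1": p1, "p2": p2, "mask": mask,
                "e1w": e1w, "e2w": e2w, "e1n": e1n, "e2n": e2n,
                "types": types, "dist": dist, "cnt": cnt, "labels": labels,
                "sents": [inst.window for inst in instances]}

    # ------------------------------------------------------------- forward
    def input_repr(self, batch: dict, train: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
        """Concatenated word/POS/position token features (B, T, D)."""
        x = concat([self.word_emb(batch["word"]),
                    self.pos_emb(batch["pos"]),
                    self.pos1_emb(batch["p1"]),
                    self.pos2_emb(batch["p2"])], axis=2)
        x = x * Tensor(batch["mask"][:, :, None])
        return dropout(x, self.config.dropout, rng, train)

    def encode(self, batch: dict, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Per-token hidden vectors (B, T, 2*lstm_hidden [+ extra])."""
        if self.encode_hook is not None:
            return self.encode_hook(batch, train, rng)
        h = self.input_repr(batch, train=train, rng=rng)
        for lstm in self.lstms:
            h = lstm(h, batch["mask"])
        return h

    def side_features(self, batch: dict) -> Tensor:
        """Entity words (mean over mention tokens), types and bucketed
        distance/count embeddings, concatenated."""
        m1 = Tensor((batch["e1w"] != 0).astype(float)[:, :, None])
        m2 = Tensor((batch["e2w"] != 0).astype(float)[:, :, None])
        e1 = (self.word_emb(batch["e1w"]) * m1).sum(axis=1) \
            * Tensor(1.0 / batch["e1n"][:, None])
        e2 = (self.word_emb(batch["e2w"]) * m2).sum(axis=1) \
            * Tensor(1.0 / batch["e2n"][:, None])
        t = self.type_emb(batch["types"])
        t = t.reshape(t.shape[0], -1)
        d = self.dist_emb(batch["dist"])
        c = self.count_emb(batch["cnt"])
        return concat([e1, e2, t, d, c], axis=1)

    def logits(self, batch: dict, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        h = self.encode(batch, train=train, rng=rng)
        ctx, _ = attention_pool(h, self.att_W, self.att_v, batch["mask"])
        if self.ctx_extra_hook is not None:
            ctx = concat([ctx, self.ctx_extra_hook(batch, train, rng)],
                         axis=1)
        ctx = dropout(ctx, self.config.dropout, rng, train)
        return self.out(concat([ctx, self.side_features(batch)], axis=1))

    def predict_proba(self, instances: list[RelationInstance]) -> np.ndarray:
        """(N, 8) class probabilities, rows summing to 1."""
        if not self.trained:
            raise UntrainedModelError("ReModel.fit has not been run")
        out = []
        bs = self.config.batch_size
        for lo in range(0, len(instances), bs):
            chunk = instances[lo:lo + bs]
            probs = softmax(self.logits(self.featurize(chunk)), axis=1)
            out.append(probs.data)
        return np.concatenate(out, axis=0)

    @staticmethod
    def decide(probs: np.ndarray) -> int:
        """Argmax with ties resolved conservatively to "None" (class 0)."""
        maxv = probs.max()
        tied = np.flatnonzero(probs >= maxv - 1e-12)
        return 0 if 0 in tied else int(tied[0])

    # ------------------------------------------------------------ training
    def fit(self, docs: list[Document], log: list | None = None) -> list:
        cfg = self.config
        instances = prepare_re_data(docs, cfg.max_sentence_gap,
                                    cfg.negative_keep, cfg.seed)
        self.build(instances)
        trainer_rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self.parameters(), lr=cfg.learning_rate)
        log = [] if log is None else log
        for epoch in range(cfg.epochs):
            order = trainer_rng.permutation(len(instances))
            total, nb = 0.0, 0
            for lo in range(0, len(order), cfg.batch_size):
                chunk = [instances[i] for i in order[lo:lo + cfg.batch_size]]
                batch = self.featurize(chunk)
                self.zero_grad()
                loss = cross_entropy(
                    self.logits(batch, train=True, rng=trainer_rng),
                    batch["labels"])
                loss.backward()
                opt.step()
                total += loss.item()
                nb += 1
            log.append({"task": "re", "epoch": epoch,
                        "loss": total / max(nb, 1)})
        self.trained = True
        return log

    # -------------------------------------------------------- persistence
    def save(self, path: str):
        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "config.json"), "w") as fh:
            json.dump({"config": asdict(self.config),
                       "trained": self.trained,
                       "hidden_extra": self.hidden_extra,
                       "out_extra": self.out_extra,
                       "word_vocab": self.word_vocab.to_json(),
                       "pos_vocab": self.pos_vocab.to_json()}, fh)
        np.savez(os.path.join(path, "params.npz"), **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "ReModel":
        with open(os.path.join(path, "config.json")) as fh:
            meta = json.load(fh)
        model = cls(ReConfig(**meta["config"]))
        model.word_vocab = Vocab.from_json(meta["word_vocab"])
        model.pos_vocab = Vocab.from_json(meta["pos_vocab"])
        model.build([], hidden_extra=meta.get("hidden_extra", 0),
                    out_extra=meta.get("out_extra", 0))
        model.load_state_dict(dict(np.load(os.path.join(path, "params.npz"))))
        model.trained = meta["trained"]
        return model


def prepare_re_data(docs: list[Document], max_sentence_gap: int,
                    negative_keep: float = 1.0,
                    seed: int = 0) -> list[RelationInstance]:
    """Candidate instances over gold documents, optionally down-sampling
    the "None" class at ratio `negative_keep`."""
    rng = np.random.default_rng(seed + 7)
    out: list[RelationInstance] = []
    for doc in docs:
        sentences = [pos_tag(s) for s in tokenize_and_split(doc.text)]
        for inst in build_relation_candidates(doc, sentences,
                                              max_sentence_gap):
            if inst.label == "None" and negative_keep < 1.0 \
                    and rng.random() > negative_keep:
                continue
            out.append(inst)
    return out


def extract_relations(doc: Document, entities: list[Entity], model: ReModel,
                      max_sentence_gap: int | None = None) -> list[Relation]:
    """Classify all candidates over `entities` and keep positive decisions.

    A pair is emitted only when the predicted class equals the single
    relation type its entity types admit, so the output always satisfies
    the schema signatures.
    """
    gap = max_sentence_gap if max_sentence_gap is not None \
        else model.config.max_sentence_gap
    shadow = Document(doc_id=doc.doc_id, text=doc.text,
                      entities=list(entities), relations=[], split=doc.split)
    sentences = [pos_tag(s) for s in tokenize_and_split(doc.text)]
    cands = build_relation_candidates(shadow, sentences, gap)
    if not cands:
        return []
    probs = model.predict_proba(cands)
    relations: list[Relation] = []
    for inst, p in zip(cands, probs):
        cls = RELATION_CLASSES[ReModel.decide(p)]
        if cls != "None" and cls == inst.rtype_if_related:
            relations.append(Relation(id=f"R{len(relations) + 1}",
                                      rtype=cls, arg1=inst.arg1_id,
                                      arg2=inst.arg2_id))
    return relations
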