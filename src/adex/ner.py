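"""Recurrent sequence labeler for the 9 clinical entity types.

Per-token features — word embedding, initial-capital flag, part-of-speech
embedding and a character-CNN composition — are concatenated, encoded by a
(stack of) bidirectional LSTM(s) and projected to per-label emission
scores.  A linear-chain CRF over the 37 BMES-with-type labels supplies the
training objective (negative gold-path log-likelihood via the forward
recursion) and Viterbi decoding at prediction time.

The CRF primitives (`crf_sequence_score`, `crf_log_partition`,
`viterbi_decode`) are exposed both as single-sentence functions on plain
arrays, convenient for verification against exhaustive enumeration, and as
the batched tensor forms the trainer uses.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from ._autograd import Parameter, Tensor, concat, logsumexp
from .corpus import Document, Entity
from .nn import Adam, BiLSTM, CharCNN, Embedding, Linear, Module, dropout
from .preprocessing import (LABELS, LABEL_TO_ID, Token, Vocab, encode_bmes,
                            decode_bmes, pos_tag, rebind_surface,
                            tokenize_and_split)

__all__ = [
    "NerConfig", "NerModel", "crf_sequence_score", "crf_log_partition",
    "crf_nll", "viterbi_decode", "bmes_transition_mask",
]

N_LABELS = len(LABELS)          # 37
START, STOP = N_LABELS, N_LABELS + 1
MAX_WORD_LEN = 20
NEG_INF = -1e4


@dataclass
class NerConfig:
    word_dim: int = 48
    char_dim: int = 16
    char_cnn_filters: int = 24
    char_cnn_kernel: int = 3
    pos_dim: int = 10
    capital_dim: int = 4
    lstm_hidden: int = 48        # per direction
    lstm_layers: int = 1
    dropout: float = 0.2
    learning_rate: float = 2e-3
    batch_size: int = 32
    epochs: int = 5
    seed: int = 0
    constrain_decode: bool = False  # mask structurally impossible transitions
    lowercase: bool = True

    def validate(self):
        dims = (self.word_dim, self.char_dim, self.char_cnn_filters,
                self.char_cnn_kernel, self.pos_dim, self.capital_dim,
                self.lstm_hidden, self.lstm_layers, self.batch_size)
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# ----------------------------------------------------------- CRF primitives

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def crf_sequence_score_batch(emissions: Tensor, transitions: Tensor,
                             labels: np.ndarray, mask: np.ndarray) -> Tensor:
    """Path scores for right-padded batches; returns a (B,) tensor.

    START/STOP rows sit at indices L and L+1 of the (L+2, L+2)
    transition matrix, where L is the emission width."""
    B, T, L = emissions.shape
    start, stop = L, L + 1
    b_idx = np.arange(B)
    lengths = mask.sum(axis=1).astype(int)
    emit = emissions.take((np.repeat(b_idx, T), np.tile(np.arange(T), B),
                           labels.reshape(-1))).reshape(B, T)
    score = (emit * Tensor(mask)).sum(axis=1)
    score = score + transitions.take((np.full(B, start), labels[:, 0]))
    for t in range(1, T):
        step = transitions.take((labels[:, t - 1], labels[:, t]))
        score = score + step * Tensor(mask[:, t])
    last = labels[b_idx, lengths - 1]
    score = score + transitions.take((last, np.full(B, stop)))
    return score


def crf_log_partition_batch(emissions: Tensor, transitions: Tensor,
                            mask: np.ndarray) -> Tensor:
    """Forward-algorithm log partition for right-padded batches; (B,)."""
    B, T, L = emissions.shape
    start = transitions[(L, slice(0, L))]
    inner = transitions[(slice(0, L), slice(0, L))]
    stop = transitions[(slice(0, L), L + 1)]
    alpha = emissions[:, 0, :] + start
    for t in range(1, T):
        scores = alpha.reshape(B, L, 1) + inner.reshape(1, L, L) \
            + emissions[:, t, :].reshape(B, 1, L)
        new = logsumexp(scores, axis=1)
        m = Tensor(mask[:, t:t + 1])
        alpha = m * new + (1.0 - m) * alpha
    return logsumexp(alpha + stop, axis=1)


def crf_sequence_score(emissions, transitions, labels) -> float:
    """Score of one labeling of one sentence: emission scores along the
    path plus transitions including START→l1 and ln→STOP."""
    e = np.asarray(emissions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, L = e.shape
    if labels.shape != (n,):
        raise ValueError("labels length must match the sentence")
    if labels.min() < 0 or labels.max() >= L:
        raise IndexError("label index out of range")
    out = crf_sequence_score_batch(
        _as_tensor(e[None]), _as_tensor(np.asarray(transitions, dtype=float)),
        labels[None], np.ones((1, n)))
    return float(out.data[0])


def crf_log_partition(emissions, transitions) -> float:
    """log Σ over all label sequences of exp(sequence score)."""
    e = np.asarray(emissions, dtype=float)
    out = crf_log_partition_batch(
        _as_tensor(e[None]), _as_tensor(np.asarray(transitions, dtype=float)),
        np.ones((1, e.shape[0])))
    return float(out.data[0])


def crf_nll(emissions: Tensor, transitions: Tensor, labels: np.ndarray,
            mask: np.ndarray) -> Tensor:
    """Mean over sentences of log-partition minus gold score (≥ 0)."""
    logz = crf_log_partition_batch(emissions, transitions, mask)
    gold = crf_sequence_score_batch(emissions, transitions, labels, mask)
    return (logz - gold).mean()


def viterbi_decode(emissions, transitions,
                   constraint_mask: np.ndarray | None = None
                   ) -> tuple[list[int], float]:
    """Best-scoring label path and its score for one sentence.

    Ties are broken toward the lowest label index at every backpointer.
    An optional (L+2, L+2) boolean `constraint_mask` (True = allowed)
    forbids transitions by adding a large negative score.
    """
    e = np.asarray(emissions, dtype=float)
    tr = np.asarray(transitions, dtype=float).copy()
    n, L = e.shape
    if constraint_mask is not None:
        tr = tr + np.where(constraint_mask, 0.0, NEG_INF)
    score = tr[L, :L] + e[0]
    backs = []
    for t in range(1, n):
        cand = score[:, None] + tr[:L, :L]
        best = np.argmax(cand, axis=0)  # argmax → first (lowest) index
        backs.append(best)
        score = cand[best, np.arange(L)] + e[t]
    final = score + tr[:L, L + 1]
    last = int(np.argmax(final))
    total = float(final[last])
    path = [last]
    for best in reversed(backs):
        path.append(int(best[path[-1]]))
    path.reverse()
    return path, total


def bmes_transition_mask() -> np.ndarray:
    """(L+2, L+2) boolean matrix of structurally valid BMES transitions."""
    ok = np.zeros((N_LABELS + 2, N_LABELS + 2), dtype=bool)

    def opens(j):  # labels that may start at any boundary
        lab = LABELS[j]
        return lab == "O" or lab.startswith(("B_", "S_"))

    def closed(i):  # labels after which an entity boundary exists
        lab = LABELS[i]
        return lab == "O" or lab.startswith(("E_", "S_"))

    for i, lab_i in enumerate(LABELS):
        for j, lab_j in enumerate(LABELS):
            if lab_i.startswith(("B_", "M_")):
                t = lab_i[2:]
                ok[i, j] = lab_j in (f"M_{t}", f"E_{t}")
            else:
                ok[i, j] = opens(j)
    for j in range(N_LABELS):
        ok[START, j] = opens(j)
    for i in range(N_LABELS):
        ok[i, STOP] = closed(i)
    return ok


# ------------------------------------------------------------------- model

class UntrainedModelError(RuntimeError):
    pass


class NerModel(Module):
    """BiLSTM-CRF tagger bundling vocabularies, parameters and config."""

    def __init__(self, config: NerConfig | None = None):
        self.config = config or NerConfig()
        self.config.validate()
        cfg = self.config
        self.rng = np.random.default_rng(cfg.seed)
        self.word_vocab = Vocab()
        self.char_vocab = Vocab()
        self.pos_vocab = Vocab()
        self.trained = False
        self._frozen_words = False
        self._built = False
        self.proj_extra = 0
        #: optional (batch, train, rng) -> emissions override; the
        #: multi-task couplings plug their widened encoders in here
        self.encode_hook = None

    # -------------------------------------------------------- construction
    def build(self, sentences: list[list[Token]],
              pretrained: dict[str, np.ndarray] | None = None,
              freeze_pretrained: bool = True, proj_extra: int = 0):
        """Build vocabularies from training sentences and allocate
        parameters.  Optional `pretrained` maps words to vectors of
        ``word_dim``; matched rows are copied in and, by default, frozen.
        `proj_extra` widens the emission projection input for encoders
        that append coupled representations."""
        cfg = self.config
        for sent in sentences:
            for tok in sent:
                self.word_vocab.add(self._norm(tok.text))
                self.pos_vocab.add(tok.pos)
                for ch in tok.text[:MAX_WORD_LEN]:
                    self.char_vocab.add(ch)
        rng = self.rng
        self.word_emb = Embedding(len(self.word_vocab), cfg.word_dim, rng)
        self.pos_emb = Embedding(len(self.pos_vocab), cfg.pos_dim, rng)
        self.cap_emb = Embedding(3, cfg.capital_dim, rng)
        self.char_cnn = CharCNN(len(self.char_vocab), cfg.char_dim,
                                cfg.char_cnn_filters, cfg.char_cnn_kernel, rng)
        in_dim = (cfg.word_dim + cfg.char_cnn_filters + cfg.pos_dim
                  + cfg.capital_dim)
        self.lstms = []
        for layer in range(cfg.lstm_layers):
            self.lstms.append(BiLSTM(in_dim if layer == 0
                                     else 2 * cfg.lstm_hidden,
                                     cfg.lstm_hidden, rng))
        self.proj_extra = proj_extra
        self.proj = Linear(2 * cfg.lstm_hidden + proj_extra, N_LABELS, rng)
        self.transitions = Parameter(rng.normal(0, 0.01,
                                                (N_LABELS + 2, N_LABELS + 2)))
        if pretrained:
            hit = 0
            for word, idx in self.word_vocab._idx.items():
                vec = pretrained.get(word)
                if vec is not None and len(vec) == cfg.word_dim:
                    self.word_emb.weight.data[idx] = vec
                    hit += 1
            self._frozen_words = freeze_pretrained and hit > 0
        self._built = True

    def _norm(self, text: str) -> str:
        return text.lower() if self.config.lowercase else text

    def trainable_parameters(self):
        skip = {id(self.word_emb.weight)} if self._frozen_words else set()
        return [p for p in self.parameters() if id(p) not in skip]

    # ------------------------------------------------------------ batching
    def featurize(self, sentences: list[list[Token]],
                  labels: list[list[str]] | None = None):
        """Pad a list of sentences into index arrays for the encoder."""
        B = len(sentences)
        T = max(len(s) for s in sentences)
        W = min(MAX_WORD_LEN, max(len(t.text) for s in sentences for t in s))
        W = max(W, self.config.char_cnn_kernel)
        word = np.zeros((B, T), dtype=np.intp)
        pos = np.zeros((B, T), dtype=np.intp)
        cap = np.zeros((B, T), dtype=np.intp)
        chars = np.zeros((B, T, W), dtype=np.intp)
        mask = np.zeros((B, T))
        lab = np.zeros((B, T), dtype=np.intp)
        for i, sent in enumerate(sentences):
            for j, tok in enumerate(sent):
                word[i, j] = self.word_vocab[self._norm(tok.text)]
                pos[i, j] = self.pos_vocab[tok.pos]
                cap[i, j] = 2 if tok.initial_capital else 1
                for k, ch in enumerate(tok.text[:W]):
                    chars[i, j, k] = self.char_vocab[ch]
                mask[i, j] = 1.0
            if labels is not None:
                for j, s in enumerate(labels[i]):
                    lab[i, j] = LABEL_TO_ID[s]
        return {"word": word, "pos": pos, "cap": cap, "chars": chars,
                "mask": mask, "labels": lab if labels is not None else None,
                "sents": sentences}

    # ------------------------------------------------------------- encoder
    def input_repr(self, batch: dict, train: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
        """Concatenated word/capital/POS/char token features (B, T, D)."""
        cfg = self.config
        B, T = batch["word"].shape
        w = self.word_emb(batch["word"])
        p = self.pos_emb(batch["pos"])
        c = self.cap_emb(batch["cap"])
        ch = self.char_cnn(batch["chars"].reshape(B * T, -1))
        ch = ch.reshape(B, T, cfg.char_cnn_filters)
        x = concat([w, c, p, ch], axis=2)
        x = x * Tensor(batch["mask"][:, :, None])
        return dropout(x, cfg.dropout, rng, train)

    def hidden(self, batch: dict, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        h = self.input_repr(batch, train=train, rng=rng)
        for lstm in self.lstms:
            h = lstm(h, batch["mask"])
        return h

    def encode(self, batch: dict, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Emission scores (B, T, 37) from padded feature arrays."""
        if self.encode_hook is not None:
            return self.encode_hook(batch, train, rng)
        h = self.hidden(batch, train=train, rng=rng)
        h = dropout(h, self.config.dropout, rng, train)
        return self.proj(h)

    def char_representation(self, token_text: str) -> np.ndarray:
        """Character-CNN vector for one token (length char_cnn_filters)."""
        if not token_text:
            raise ValueError("token text must be non-empty")
        if not self._built:
            raise UntrainedModelError("model has no parameters yet")
        W = max(len(token_text[:MAX_WORD_LEN]), self.config.char_cnn_kernel)
        idx = np.zeros((1, W), dtype=np.intp)
        for k, chr_ in enumerate(token_text[:MAX_WORD_LEN]):
            idx[0, k] = self.char_vocab[chr_]
        return self.char_cnn(idx).data[0].copy()

    # ------------------------------------------------------------ training
    def loss_on(self, batch: dict, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        emissions = self.encode(batch, train=train, rng=rng)
        return crf_nll(emissions, self.transitions, batch["labels"],
                       batch["mask"])

    def fit(self, docs: list[Document], log: list | None = None) -> list:
        """Train on gold-annotated documents; returns the per-epoch log."""
        data = prepare_ner_data(docs)
        self.build([s for s, _ in data])
        trainer_rng = np.random.default_rng(self.config.seed + 1)
        opt = Adam(self.trainable_parameters(), lr=self.config.learning_rate)
        log = [] if log is None else log
        for epoch in range(self.config.epochs):
            order = trainer_rng.permutation(len(data))
            total, nb = 0.0, 0
            for lo in range(0, len(order), self.config.batch_size):
                idx = order[lo:lo + self.config.batch_size]
                sents = [data[i][0] for i in idx]
                labs = [data[i][1] for i in idx]
                batch = self.featurize(sents, labs)
                self.zero_grad()
                loss = self.loss_on(batch, train=True, rng=trainer_rng)
                loss.backward()
                opt.step()
                total += loss.item()
                nb += 1
            log.append({"task": "ner", "epoch": epoch,
                        "loss": total / max(nb, 1)})
        self.trained = True
        return log

    # ----------------------------------------------------------- inference
    def predict_labels(self, sentences: list[list[Token]]) -> list[list[str]]:
        if not self.trained:
            raise UntrainedModelError("NerModel.fit has not been run")
        cmask = bmes_transition_mask() if self.config.constrain_decode else None
        out = []
        for lo in range(0, len(sentences), self.config.batch_size):
            chunk = sentences[lo:lo + self.config.batch_size]
            batch = self.featurize(chunk)
            emissions = self.encode(batch).data
            for i, sent in enumerate(chunk):
                path, _ = viterbi_decode(emissions[i, :len(sent)],
                                         self.transitions.data, cmask)
                out.append([LABELS[k] for k in path])
        return out

    def predict_entities(self, doc: Document) -> list[Entity]:
        """Tag a raw document: tokenize, decode BMES, emit offset entities."""
        sentences = [pos_tag(s) for s in tokenize_and_split(doc.text)]
        if not sentences:
            return []
        ents: list[Entity] = []
        for sent, labels in zip(sentences, self.predict_labels(sentences)):
            for e in decode_bmes(labels, sent):
                ents.append(Entity(id=f"T{len(ents) + 1}", etype=e.etype,
                                   start=e.start, end=e.end, text=e.text))
        return rebind_surface(ents, doc.text)

    # -------------------------------------------------------- persistence
    def save(self, path: str):
        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "config.json"), "w") as fh:
            json.dump({"config": asdict(self.config),
                       "trained": self.trained,
                       "proj_extra": self.proj_extra,
                       "word_vocab": self.word_vocab.to_json(),
                       "char_vocab": self.char_vocab.to_json(),
                       "pos_vocab": self.pos_vocab.to_json()}, fh)
        np.savez(os.path.join(path, "params.npz"), **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "NerModel":
        with open(os.path.join(path, "config.json")) as fh:
            meta = json.load(fh)
        cfg = NerConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in meta["config"].items()})
        model = cls(cfg)
        model.word_vocab = Vocab.from_json(meta["word_vocab"])
        model.char_vocab = Vocab.from_json(meta["char_vocab"])
        model.pos_vocab = Vocab.from_json(meta["pos_vocab"])
        model.build([], proj_extra=meta.get("proj_extra", 0))
        state = dict(np.load(os.path.join(path, "params.npz")))
        model.load_state_dict(state)
        model.trained = meta["trained"]
        return model


def prepare_ner_data(docs: list[Document]
                     ) -> list[tuple[list[Token], list[str]]]:
    """Tokenize, tag and BMES-encode gold documents into training pairs."""
    out = []
    for doc in docs:
        for sent in tokenize_and_split(doc.text):
            pos_tag(sent)
            in_sent = [e for e in doc.entities
                       if e.start < sent[-1].end and e.end > sent[0].start]
            out.append((sent, encode_bmes(sent, in_sent)))
    return out


def load_word2vec_text(path: str) -> dict[str, np.ndarray]:
    """Read whitespace 'word v1 ... vd' embeddings; a numeric header line
    (count dim) is skipped if present."""
    table: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip().split()
            if not parts:
                continue
            if i == 0 and len(parts) == 2 and all(p.isdigit() for p in parts):
                continue
            table[parts[0]] = np.asarray([float(x) for x in parts[1:]])
    return table
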