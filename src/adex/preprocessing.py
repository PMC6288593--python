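"""Tokenization, sentence splitting, BMES span coding, relation-candidate
generation and vocabularies shared by the tagging and relation models.

Span coding uses the BMES scheme: a multi-token entity of type ``t`` becomes
``B_t, M_t, ..., E_t``; a single-token entity becomes ``S_t``; everything
else is ``O``.  With 9 entity types the label alphabet has 37 symbols.

The bundled part-of-speech tagger is a deterministic rule system
(closed-class lexicon + suffix heuristics) so the package needs no model
download; any callable with the same signature can be plugged in instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus import ENTITY_TYPES, RELATION_SIGNATURES, Document, Entity

__all__ = [
    "Token", "RelationInstance", "LABELS", "LABEL_TO_ID",
    "tokenize_and_split", "pos_tag", "encode_bmes", "decode_bmes",
    "align_entity", "build_relation_candidates", "compute_positions",
    "Vocab", "bucket_distance", "DISTANCE_BUCKETS",
]

# ---------------------------------------------------------------- label set

LABELS: tuple[str, ...] = ("O",) + tuple(
    f"{p}_{t}" for t in ENTITY_TYPES for p in "BMES")
LABEL_TO_ID: dict[str, int] = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class Token:
    text: str
    start: int
    end: int
    pos: str = ""
    initial_capital: bool = False
    sentence_index: int = 0
    token_index: int = 0


# ------------------------------------------------------------- tokenization

_TOKEN_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?|\d+(?:\.\d+)?|\S")
_SENT_END = {".", "!", "?"}


def tokenize_and_split(text: str) -> list[list[Token]]:
    """Split `text` into sentences of offset-annotated tokens.

    Sentences end after ``. ! ?`` tokens or across blank/newline gaps.
    Returns an empty list for empty input.  Offsets always satisfy
    ``text[tok.start:tok.end] == tok.text``.
    """
    sentences: list[list[Token]] = []
    current: list[Token] = []
    last_end = 0
    global_idx = 0
    for m in _TOKEN_RE.finditer(text):
        if current and "\n" in text[last_end:m.start()]:
            sentences.append(current)
            current = []
        tok = Token(text=m.group(), start=m.start(), end=m.end(),
                    initial_capital=m.group()[0].isupper(),
                    sentence_index=len(sentences), token_index=global_idx)
        current.append(tok)
        global_idx += 1
        last_end = m.end()
        if tok.text in _SENT_END:
            sentences.append(current)
            current = []
    if current:
        sentences.append(current)
    return sentences


# ----------------------------------------------------------------- POS tags

_LEXICON = {
    "the": "DT", "a": "DT", "an": "DT",
    "of": "IN", "in": "IN", "on": "IN", "for": "IN", "with": "IN",
    "after": "IN", "before": "IN", "to": "IN", "from": "IN", "by": "IN",
    "at": "IN", "during": "IN", "per": "IN", "without": "IN", "as": "IN",
    "and": "CC", "or": "CC", "but": "CC",
    "he": "PRP", "she": "PRP", "it": "PRP", "they": "PRP", "we": "PRP",
    "i": "PRP", "you": "PRP", "his": "PRP$", "her": "PRP$", "their": "PRP$",
    "patient": "NN", "day": "NN", "days": "NNS", "weeks": "NNS",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "has": "VBZ", "had": "VBD", "have": "VBP",
    "will": "MD", "would": "MD", "may": "MD", "might": "MD", "can": "MD",
    "could": "MD", "should": "MD", "must": "MD",
    "not": "RB", "no": "DT",
}

_JJ_SUFFIX = ("al", "ous", "ic", "ive", "ar", "ary", "ile", "oid")
_NN_SUFFIX = ("tion", "sion", "ment", "ness", "ity", "emia", "itis",
              "osis", "pathy", "algia", "uria", "rrhea")


def _tag_one(text: str, sentence_initial: bool) -> str:
    if not any(c.isalnum() for c in text):
        if text in _SENT_END:
            return "."
        return "," if text == "," else "SYM"
    low = text.lower()
    if low in _LEXICON:
        return _LEXICON[low]
    if text[0].isdigit():
        return "CD"
    if low.endswith("ly"):
        return "RB"
    if low.endswith("ing") and len(low) > 4:
        return "VBG"
    if low.endswith("ed") and len(low) > 3:
        return "VBD"
    for suf in _JJ_SUFFIX:
        if low.endswith(suf) and len(low) > len(suf) + 1:
            return "JJ"
    for suf in _NN_SUFFIX:
        if low.endswith(suf) and len(low) > len(suf) + 1:
            return "NN"
    if text[0].isupper() and not sentence_initial:
        return "NNP"
    if low.endswith("s") and not low.endswith("ss") and len(low) > 3:
        return "NNS"
    return "NN"


def pos_tag(sentence: list[Token]) -> list[Token]:
    """Fill ``tok.pos`` in place (and return the sentence) with tags from a
    deterministic rule tagger over a Penn-style tagset."""
    for i, tok in enumerate(sentence):
        tok.pos = _tag_one(tok.text, sentence_initial=(i == 0))
    return sentence


# ------------------------------------------------------------- BMES coding

class OverlapError(ValueError):
    """Two entities overlap on the same token."""


def align_entity(entity: Entity, tokens: list[Token]) -> tuple[int, int] | None:
    """Smallest covering token span [i, j] for a character span, or None if
    no token overlaps it."""
    idx = [k for k, t in enumerate(tokens)
           if t.start < entity.end and t.end > entity.start]
    if not idx:
        return None
    return idx[0], idx[-1]


def encode_bmes(sentence: list[Token], entities: list[Entity],
                snap_report: list | None = None) -> list[str]:
    """Encode entity spans over one sentence as BMES labels.

    Entity character spans that do not sit exactly on token boundaries are
    snapped outward to the smallest covering token span; each snap is
    appended to `snap_report` when given.  Entities overlapping on a token
    raise :class:`OverlapError`.
    """
    labels = ["O"] * len(sentence)
    owner: list[Entity | None] = [None] * len(sentence)
    for ent in entities:
        span = align_entity(ent, sentence)
        if span is None:
            continue
        i, j = span
        if (sentence[i].start, sentence[j].end) != (ent.start, ent.end) \
                and snap_report is not None:
            snap_report.append((ent.id, (ent.start, ent.end),
                                (sentence[i].start, sentence[j].end)))
        for k in range(i, j + 1):
            if owner[k] is not None:
                raise OverlapError(
                    f"entities {owner[k].id} and {ent.id} overlap on token "
                    f"{sentence[k].text!r}")
            owner[k] = ent
        if i == j:
            labels[i] = f"S_{ent.etype}"
        else:
            labels[i] = f"B_{ent.etype}"
            for k in range(i + 1, j):
                labels[k] = f"M_{ent.etype}"
            labels[j] = f"E_{ent.etype}"
    return labels


def decode_bmes(labels: list[str], sentence: list[Token]) -> list[Entity]:
    """Decode BMES labels back to character-offset entities.

    Ill-formed sequences are repaired strict-left: an ``M``/``E`` with no
    live ``B`` run of the same type to its left becomes ``O``; a ``B`` run
    that never reaches its ``E`` is truncated at the last contiguous
    same-type ``M`` (a lone ``B`` yields a single-token entity).
    """
    assert len(labels) == len(sentence)
    out: list[Entity] = []
    i, n = 0, len(labels)
    while i < n:
        lab = labels[i]
        if lab.startswith("S_"):
            t = lab[2:]
            out.append(_make_entity(sentence, i, i, t, len(out)))
            i += 1
        elif lab.startswith("B_"):
            t = lab[2:]
            j = i
            while j + 1 < n and labels[j + 1] == f"M_{t}":
                j += 1
            if j + 1 < n and labels[j + 1] == f"E_{t}":
                j += 1
            out.append(_make_entity(sentence, i, j, t, len(out)))
            i = j + 1
        else:  # O, or a stray M/E with no opener: repaired to O
            i += 1
    return out


def _make_entity(sentence: list[Token], i: int, j: int, etype: str,
                 k: int) -> Entity:
    start, end = sentence[i].start, sentence[j].end
    # surface text must be reconstructed by the caller against the document;
    # tokens carry enough to do it losslessly for contiguous spans
    text = " ".join(t.text for t in sentence[i:j + 1])
    return Entity(id=f"T{k + 1}", etype=etype, start=start, end=end, text=text)


def rebind_surface(entities: list[Entity], text: str) -> list[Entity]:
    """Replace approximate surface strings with exact document substrings."""
    return [Entity(e.id, e.etype, e.start, e.end, text[e.start:e.end])
            for e in entities]


# ------------------------------------------------- relation candidates

@dataclass
class RelationInstance:
    """One ordered, type-compatible entity pair with its context window.

    ``e1``/``e2`` are in textual order; ``rtype_if_related`` is the unique
    schema relation the pair could bear, with ``arg1_id``/``arg2_id``
    already in canonical signature order.  ``label`` is that relation name
    for gold-positive pairs and ``"None"`` otherwise.
    """
    doc_id: str
    e1: Entity
    e2: Entity
    arg1_id: str
    arg2_id: str
    rtype_if_related: str
    window: list[Token] = field(default_factory=list)
    span1: tuple[int, int] = (0, 0)  # token-index span of e1 in window
    span2: tuple[int, int] = (0, 0)
    positions1: list[int] = field(default_factory=list)
    positions2: list[int] = field(default_factory=list)
    sentence_gap: int = 0
    token_distance: int = 0
    entity_count_between: int = 0
    label: str = "None"


def compute_positions(n: int, span: tuple[int, int]) -> list[int]:
    """Signed distance of each window index to the span: negative before,
    zero inside, positive after."""
    s, e = span
    return [i - s if i < s else (0 if i <= e else i - e) for i in range(n)]


def _signature_orientation(a: Entity, b: Entity) -> tuple[str, str, str] | None:
    for rtype, (t1, t2) in RELATION_SIGNATURES.items():
        if (a.etype, b.etype) == (t1, t2):
            return rtype, a.id, b.id
        if (b.etype, a.etype) == (t1, t2):
            return rtype, b.id, a.id
    return None


def build_relation_candidates(
        doc: Document, sentences: list[list[Token]],
        max_sentence_gap: int = 3) -> list[RelationInstance]:
    """Enumerate type-compatible entity pairs within `max_sentence_gap`
    sentences and attach context windows, positions and gold labels.

    The window runs from the first token of the earlier entity's sentence
    to the last token of the later entity's sentence, so inter-sentence
    pairs see the full intervening context.
    """
    all_tokens = [t for s in sentences for t in s]
    spans: dict[str, tuple[int, int]] = {}
    sent_of: dict[str, int] = {}
    for ent in doc.entities:
        span = align_entity(ent, all_tokens)
        if span is None:
            continue
        spans[ent.id] = span
        sent_of[ent.id] = all_tokens[span[0]].sentence_index
    gold = {(r.arg1, r.arg2): r.rtype for r in doc.relations}
    sent_starts = [s[0].token_index for s in sentences]
    sent_ends = [s[-1].token_index for s in sentences]
    ordered = sorted((e for e in doc.entities if e.id in spans),
                     key=lambda e: (e.start, e.end))
    out: list[RelationInstance] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            orient = _signature_orientation(a, b)
            if orient is None:
                continue
            gap = abs(sent_of[a.id] - sent_of[b.id])
            if gap > max_sentence_gap:
                continue
            rtype, arg1, arg2 = orient
            lo_sent = min(sent_of[a.id], sent_of[b.id])
            hi_sent = max(sent_of[a.id], sent_of[b.id])
            w0, w1 = sent_starts[lo_sent], sent_ends[hi_sent]
            window = all_tokens[w0:w1 + 1]
            s1 = (spans[a.id][0] - w0, spans[a.id][1] - w0)
            s2 = (spans[b.id][0] - w0, spans[b.id][1] - w0)
            n = len(window)
            between = sum(1 for c in ordered
                          if c.id not in (a.id, b.id)
                          and c.start >= a.end and c.end <= b.start)
            inst = RelationInstance(
                doc_id=doc.doc_id, e1=a, e2=b, arg1_id=arg1, arg2_id=arg2,
                rtype_if_related=rtype, window=window, span1=s1, span2=s2,
                positions1=compute_positions(n, s1),
                positions2=compute_positions(n, s2),
                sentence_gap=gap,
                token_distance=max(0, s2[0] - s1[1] - 1),
                entity_count_between=between,
                label=gold.get((arg1, arg2), "None"))
            out.append(inst)
    return out


# ------------------------------------------------------------- vocabularies

DISTANCE_BUCKETS: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 1), (2, 2), (3, 5), (6, 10), (11, 10**9))


def bucket_distance(d: int) -> int:
    """Map a non-negative count to its bucket index in DISTANCE_BUCKETS."""
    for i, (lo, hi) in enumerate(DISTANCE_BUCKETS):
        if lo <= d <= hi:
            return i
    raise ValueError(f"negative distance {d}")


class Vocab:
    """String → contiguous index map with reserved PAD (0) and UNK (1)."""

    PAD, UNK = 0, 1

    def __init__(self, items=(), specials: bool = True):
        self.specials = specials
        self._idx: dict[str, int] = {}
        if specials:
            self._idx["<pad>"] = 0
            self._idx["<unk>"] = 1
        for it in items:
            self.add(it)

    def add(self, item: str) -> int:
        if item not in self._idx:
            self._idx[item] = len(self._idx)
        return self._idx[item]

    def __getitem__(self, item: str) -> int:
        if item in self._idx:
            return self._idx[item]
        if self.specials:
            return self.UNK
        raise KeyError(item)

    def __len__(self) -> int:
        return len(self._idx)

    def __contains__(self, item) -> bool:
        return item in self._idx

    def to_json(self) -> dict:
        return {"specials": self.specials, "items": list(self._idx)}

    @classmethod
    def from_json(cls, obj: dict) -> "Vocab":
        v = cls(specials=obj["specials"])
        for it in obj["items"]:
            v._idx.setdefault(it, len(v._idx))
        return v
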