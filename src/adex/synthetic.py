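"""Seeded generator of clinical-style documents in the 9-entity / 7-relation
ADE schema.

The generator emulates the statistical shape of real ADE-annotated notes —
heavy class imbalance (SSLIF sign/symptom mentions roughly ten times the
ADE mentions), attribute relations expressed by tight local patterns
("started <Medication> <Dosage> ... for <Indication>"), a configurable
fraction of Medication-ADE relations crossing sentence boundaries, and
pattern-violating distractors (ADE-vocabulary words in SSLIF contexts,
relation-sounding phrases near unrelated pairs) — without any clinical
realism beyond what exercises the extraction models.  Documents are built
token by token so every entity span is exact by construction, and a fixed
seed yields a byte-identical corpus.

The relational ground truth follows one closed rule set:

* attribute entities (Dosage, Route, Frequency, Duration, Severity) relate
  to the Medication/ADE they syntactically modify in their template;
* an Indication introduced by "for" relates to its Medication; an
  Indication in a distractor frame ("held given ...") relates to nothing;
* an ADE relates to the closest preceding in-window Medication (same
  sentence, or up to ``max_relation_gap`` sentences back).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import ENTITY_TYPES, Document, Entity, Relation
from .preprocessing import align_entity, tokenize_and_split

__all__ = ["GenConfig", "SyntheticCorpus", "generate_corpus", "corpus_stats"]

# --------------------------------------------------------------- lexicons
# Closed synthetic vocabulary: invented drug names, ordinary symptom and
# condition terms.  Pools are disjoint so that entity type is recoverable
# from context plus lexicon, except where noise deliberately mixes them.

MEDICATIONS = [
    "amlodipril", "zentamycin", "cloravir", "betaxolam", "durafenib",
    "velcatinib", "oxantrel", "midazoprene", "ferrocort", "lanoxipram",
    "quidarone", "sertaflox", "pandomide", "relizumab", "tacroligen",
    "novastatin", "ceflorin", "dexapride", "galantrex", "humirax",
    "ibrunolol", "jantoven", "ketoprazole", "lisinotril", "metformax",
    "naltrexin", "olanzaprex", "pravachex", "quetiapran", "rosuvastil",
    "sunitralin", "tamoxidol", "ustekinex", "vorinozol", "warfarex",
    "xeloderm",
]

ADE_TERMS = [
    "nausea", "vomiting", "rash", "dizziness", "neutropenia",
    "thrombocytopenia", "mucositis", "diarrhea", "pruritus", "hepatotoxicity",
    "renal failure", "peripheral neuropathy", "liver toxicity", "hives",
    "angioedema", "pancytopenia", "stomatitis", "photosensitivity",
    "hyperkalemia", "hyponatremia", "qt prolongation", "hand foot syndrome",
    "drug fever", "transaminitis", "myelosuppression", "alopecia",
    "oral ulcers", "severe bruising",
]

INDICATION_TERMS = [
    "hypertension", "diabetes", "pneumonia", "depression", "anxiety",
    "migraine", "arthritis", "cellulitis", "insomnia", "reflux",
    "anemia", "asthma", "bronchitis", "gout", "hyperlipidemia",
    "lymphoma", "myeloma", "neutropenic fever", "osteoporosis",
    "sinusitis", "thrombosis", "urinary infection", "atrial fibrillation",
    "chronic pain",
]

SSLIF_TERMS = [
    "fatigue", "fever", "chills", "cough", "back pain", "weight loss",
    "night sweats", "constipation", "chest pain", "joint stiffness",
    "tremor", "headache", "palpitations", "edema", "wheezing",
    "abdominal cramping", "blurred vision", "dry mouth", "hoarseness",
    "leg swelling", "malaise", "neck stiffness", "numbness", "pallor",
    "poor appetite", "restlessness", "rhinorrhea", "sore throat",
    "sweating", "syncope", "tinnitus", "urinary frequency", "weakness",
    "memory lapses", "gait instability", "low grade fevers",
    "dyspnea on exertion", "pleuritic discomfort", "early satiety",
    "muscle cramps",
]

SEVERITY_TERMS = ["mild", "moderate", "severe", "significant", "worsening"]
ROUTE_TERMS = ["orally", "intravenously", "subcutaneously", "topically"]
FREQUENCY_TERMS = ["daily", "twice daily", "every morning", "at bedtime",
                   "weekly", "every other day"]
DURATION_TERMS = ["2 weeks", "10 days", "3 months", "one month", "5 days",
                  "6 weeks"]
DOSAGE_AMOUNTS = ["5 mg", "10 mg", "20 mg", "25 mg", "40 mg", "50 mg",
                  "75 mg", "100 mg", "250 mg", "500 mg"]

FILLER_SENTENCES = [
    ["Vitals", "stable", "today", "."],
    ["Labs", "reviewed", "and", "unremarkable", "."],
    ["Patient", "seen", "in", "clinic", "today", "."],
    ["Plan", "discussed", "at", "length", "."],
    ["Follow", "up", "in", "two", "months", "."],
]


@dataclass
class GenConfig:
    """Knobs of the synthetic corpus.

    ``template_weights`` control the per-sentence mix of generative frames
    and hence the per-type entity rates; the default mix realizes an
    SSLIF:ADE imbalance of roughly 10:1.  ``noise_rate`` both schedules the
    distractor frame and the probability that an SSLIF surface form is
    drawn from the ADE lexicon (the lexical-overlap confound).
    """
    n_train: int = 200
    n_test: int = 50
    sentences_per_doc: tuple[int, int] = (6, 12)
    template_weights: dict = field(default_factory=lambda: {
        "med_full": 0.18, "med_duration": 0.08, "ade": 0.06,
        "sslif": 0.45, "filler": 0.13})
    intersentence_fraction: float = 0.15
    max_relation_gap: int = 2
    noise_rate: float = 0.10
    lexicon_cap: int | None = None  # truncate pools (vocab-size knob)
    seed: int = 13

    def validate(self) -> None:
        if self.n_train < 0 or self.n_test < 0:
            raise ValueError("document counts must be non-negative")
        lo, hi = self.sentences_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("sentences_per_doc range invalid")
        if not 0.0 <= self.intersentence_fraction <= 1.0:
            raise ValueError("intersentence_fraction outside [0,1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate outside [0,1]")
        if self.max_relation_gap < 1:
            raise ValueError("max_relation_gap must be >= 1")
        if any(w < 0 for w in self.template_weights.values()):
            raise ValueError("template weights must be non-negative")
        if sum(self.template_weights.values()) <= 0:
            raise ValueError("template weights sum to zero")
        if self.template_weights.get("ade", 0) == 0 and \
                self.intersentence_fraction > 0:
            raise ValueError(
                "intersentence relations require a nonzero 'ade' weight")


@dataclass
class SyntheticCorpus:
    train: list[Document]
    test: list[Document]
    tallies: dict


def _pool(cfg: GenConfig, pool: list[str]) -> list[str]:
    return pool[:cfg.lexicon_cap] if cfg.lexicon_cap else pool


class _DocBuilder:
    """Accumulates tokens/entities/relations with exact character offsets."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.pos = 0
        self.entities: list[Entity] = []
        self.relations: list[Relation] = []
        self.sent_index = 0

    def word(self, w: str):
        if self.parts and not self.parts[-1].endswith("\n"):
            self.parts.append(" ")
            self.pos += 1
        self.parts.append(w)
        self.pos += len(w)

    def entity(self, etype: str, surface: str) -> Entity:
        if self.parts and not self.parts[-1].endswith("\n"):
            self.parts.append(" ")
            self.pos += 1
        start = self.pos
        self.parts.append(surface)
        self.pos += len(surface)
        ent = Entity(id=f"T{len(self.entities) + 1}", etype=etype,
                     start=start, end=self.pos, text=surface)
        self.entities.append(ent)
        return ent

    def relate(self, rtype: str, arg1: Entity, arg2: Entity):
        self.relations.append(Relation(
            id=f"R{len(self.relations) + 1}", rtype=rtype,
            arg1=arg1.id, arg2=arg2.id))

    def end_sentence(self):
        self.word(".")
        self.parts.append("\n")
        self.pos += 1
        self.sent_index += 1

    def build(self, split: str) -> Document:
        doc = Document(doc_id=self.doc_id, text="".join(self.parts),
                       entities=self.entities, relations=self.relations,
                       split=split)
        doc.check()
        return doc


def _deck(weights: dict, n: int, rng: np.random.Generator) -> list[str]:
    """Stratified template plan: floor + stochastic-rounding allocation.

    Each category receives ``floor(w·n)`` sentences plus a Bernoulli draw
    on the fractional part, which is unbiased even for categories whose
    expected count per document is below one (the rare ADE frames).  This
    keeps the realized per-type entity rates — and hence the configured
    SSLIF:ADE imbalance — tight at a couple hundred documents.  Document
    length consequently varies by a sentence or two around `n`."""
    total = sum(weights.values())
    deck: list[str] = []
    for c in sorted(weights):
        exact = n * weights[c] / total
        k = int(exact) + (1 if rng.random() < exact - int(exact) else 0)
        deck.extend([c] * k)
    rng.shuffle(deck)
    return deck


def _gen_doc(doc_id: str, split: str, cfg: GenConfig,
             rng: np.random.Generator, tally: dict) -> Document:
    b = _DocBuilder(doc_id)
    n_sent = int(rng.integers(cfg.sentences_per_doc[0],
                              cfg.sentences_per_doc[1] + 1))
    weights = dict(cfg.template_weights)
    if cfg.noise_rate > 0:
        weights["distractor"] = cfg.noise_rate
    deck = _deck(weights, n_sent, rng)

    meds = _pool(cfg, MEDICATIONS)
    ades = _pool(cfg, ADE_TERMS)
    inds = _pool(cfg, INDICATION_TERMS)
    sslifs = _pool(cfg, SSLIF_TERMS)

    def pick(pool):
        return pool[int(rng.integers(len(pool)))]

    def count(kind, name):
        tally[kind][name] = tally[kind].get(name, 0) + 1

    def ent(etype, surface):
        count("entities", etype)
        return b.entity(etype, surface)

    def rel(rtype, a1, a2, gap):
        count("relations", rtype)
        tally["gap_histogram"][gap] = tally["gap_histogram"].get(gap, 0) + 1
        b.relate(rtype, a1, a2)

    recent_med: tuple[int, Entity] | None = None

    for cat in deck:
        s = b.sent_index
        if cat == "med_full":
            b.word("Patient")
            b.word("started")
            med = ent("Medication", pick(meds))
            dose = ent("Dosage", pick(DOSAGE_AMOUNTS))
            route = None
            if rng.random() < 0.5:
                route = ent("Route", pick(ROUTE_TERMS))
            freq = ent("Frequency", pick(FREQUENCY_TERMS))
            b.word("for")
            ind = ent("Indication", pick(inds))
            rel("Dosage-Medication", dose, med, 0)
            if route is not None:
                rel("Route-Medication", route, med, 0)
            rel("Frequency-Medication", freq, med, 0)
            rel("Medication-Indication", med, ind, 0)
            recent_med = (s, med)
        elif cat == "med_duration":
            b.word("Continued")
            med = ent("Medication", pick(meds))
            b.word("for")
            dur = ent("Duration", pick(DURATION_TERMS))
            rel("Duration-Medication", dur, med, 0)
            recent_med = (s, med)
        elif cat == "ade":
            inter = (recent_med is not None
                     and s - recent_med[0] >= 1
                     and s - recent_med[0] <= cfg.max_relation_gap
                     and rng.random() < cfg.intersentence_fraction)
            sev = None
            if inter:
                b.word("He")
                b.word("then")
                b.word("developed")
                if rng.random() < 0.5:
                    sev = ent("Severity", pick(SEVERITY_TERMS))
                ade = ent("ADE", pick(ades))
                med, gap = recent_med[1], s - recent_med[0]
            else:
                b.word("Patient")
                b.word("developed")
                if rng.random() < 0.5:
                    sev = ent("Severity", pick(SEVERITY_TERMS))
                ade = ent("ADE", pick(ades))
                b.word("after")
                b.word("starting")
                med = ent("Medication", pick(meds))
                gap = 0
                recent_med = (s, med)
            rel("Medication-ADE", med, ade, gap)
            if sev is not None:
                rel("Severity-ADE", sev, ade, 0)
        elif cat == "sslif":
            frame = int(rng.integers(3))
            noisy = rng.random() < cfg.noise_rate
            surface_pool = ades if noisy else sslifs
            if frame == 0:
                b.word("History")
                b.word("of")
                ent("SSLIF", pick(surface_pool))
            elif frame == 1:
                b.word("Exam")
                b.word("notable")
                b.word("for")
                ent("SSLIF", pick(surface_pool))
                b.word("and")
                ent("SSLIF", pick(sslifs))
            else:
                b.word("Denies")
                ent("SSLIF", pick(surface_pool))
        elif cat == "distractor":
            med = ent("Medication", pick(meds))
            b.word("was")
            b.word("held")
            b.word("given")
            ent("Indication", pick(inds))
            recent_med = (s, med)
        else:  # filler
            for w in FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))][:-1]:
                b.word(w)
        b.end_sentence()
    return b.build(split)


def generate_corpus(cfg: GenConfig) -> SyntheticCorpus:
    """Generate train/test document sets plus the generator's own tallies.

    Deterministic in ``cfg.seed``: the same config yields byte-identical
    documents.  Raises ``ValueError`` on infeasible configs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tally = {"entities": {}, "relations": {}, "gap_histogram": {}}
    train = [_gen_doc(f"synth-train-{i:04d}", "train", cfg, rng, tally)
             for i in range(cfg.n_train)]
    test = [_gen_doc(f"synth-test-{i:04d}", "test", cfg, rng, tally)
            for i in range(cfg.n_test)]
    return SyntheticCorpus(train=train, test=test, tallies=tally)


def corpus_stats(docs: list[Document]) -> dict:
    """Per-type entity and relation counts plus the relation sentence-gap
    histogram, recomputed from the documents themselves."""
    stats = {"n_docs": len(docs),
             "entities": {}, "relations": {}, "gap_histogram": {}}
    for doc in docs:
        sentences = tokenize_and_split(doc.text)
        all_tokens = [t for s in sentences for t in s]
        sent_of = {}
        for e in doc.entities:
            stats["entities"][e.etype] = stats["entities"].get(e.etype, 0) + 1
            span = align_entity(e, all_tokens)
            if span is not None:
                sent_of[e.id] = all_tokens[span[0]].sentence_index
        for r in doc.relations:
            stats["relations"][r.rtype] = stats["relations"].get(r.rtype, 0) + 1
            if r.arg1 in sent_of and r.arg2 in sent_of:
                gap = abs(sent_of[r.arg1] - sent_of[r.arg2])
                stats["gap_histogram"][gap] = \
                    stats["gap_histogram"].get(gap, 0) + 1
    return stats
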