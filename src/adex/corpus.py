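"""Data model and standoff I/O for ADE-annotated clinical documents.

The schema mirrors the MADE-style annotation task: 9 entity types
(Medication, Indication, Frequency, Severity, Dosage, Duration, Route, ADE,
SSLIF) and 7 typed binary relations, each of which fixes the entity types of
its two arguments (e.g. ``Dosage-Medication`` links a Dosage to a
Medication).  Documents are stored on disk as BRAT-style standoff: a UTF-8
``.txt`` with the raw note and a matching ``.ann`` with one annotation per
line::

    T1\tMedication 10 19\tlisinopril
    R1\tDosage-Medication Arg1:T2 Arg2:T1

Character offsets are 0-based and half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

__all__ = [
    "ENTITY_TYPES", "RELATION_TYPES", "RELATION_SIGNATURES",
    "Entity", "Relation", "Document",
    "read_standoff", "write_standoff", "validate_schema",
    "StandoffParseError", "StandoffIntegrityError", "SchemaError",
]

ENTITY_TYPES: tuple[str, ...] = (
    "Medication", "Indication", "Frequency", "Severity", "Dosage",
    "Duration", "Route", "ADE", "SSLIF",
)

#: relation name -> (arg1 entity type, arg2 entity type)
RELATION_SIGNATURES: dict[str, tuple[str, str]] = {
    "Dosage-Medication": ("Dosage", "Medication"),
    "Route-Medication": ("Route", "Medication"),
    "Frequency-Medication": ("Frequency", "Medication"),
    "Duration-Medication": ("Duration", "Medication"),
    "Medication-Indication": ("Medication", "Indication"),
    "Medication-ADE": ("Medication", "ADE"),
    "Severity-ADE": ("Severity", "ADE"),
}

RELATION_TYPES: tuple[str, ...] = tuple(RELATION_SIGNATURES)


class StandoffParseError(ValueError):
    """Malformed annotation line."""


class StandoffIntegrityError(ValueError):
    """Annotation inconsistent with the text or with other annotations."""


class SchemaError(ValueError):
    """Entity or relation type outside the closed schema."""


@dataclass(frozen=True)
class Entity:
    id: str
    etype: str
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class Relation:
    id: str
    rtype: str
    arg1: str  # Entity id
    arg2: str  # Entity id


@dataclass
class Document:
    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    split: str = "none"

    def entity_by_id(self) -> dict[str, Entity]:
        return {e.id: e for e in self.entities}

    def check(self) -> None:
        """Raise on structural invariant violations (ids, offsets, refs)."""
        ids = [e.id for e in self.entities]
        if len(ids) != len(set(ids)):
            raise StandoffIntegrityError(f"{self.doc_id}: duplicate entity ids")
        rids = [r.id for r in self.relations]
        if len(rids) != len(set(rids)):
            raise StandoffIntegrityError(f"{self.doc_id}: duplicate relation ids")
        by_id = self.entity_by_id()
        for e in self.entities:
            if not (0 <= e.start < e.end <= len(self.text)):
                raise StandoffIntegrityError(
                    f"{self.doc_id}/{e.id}: span ({e.start},{e.end}) outside text")
            if self.text[e.start:e.end] != e.text:
                raise StandoffIntegrityError(
                    f"{self.doc_id}/{e.id}: surface text mismatch at "
                    f"({e.start},{e.end})")
        for r in self.relations:
            for arg in (r.arg1, r.arg2):
                if arg not in by_id:
                    raise StandoffIntegrityError(
                        f"{self.doc_id}/{r.id}: dangling argument {arg}")
            if r.arg1 == r.arg2:
                raise StandoffIntegrityError(
                    f"{self.doc_id}/{r.id}: self-relation on {r.arg1}")


def validate_schema(doc: Document) -> list[str]:
    """Return human-readable schema violations (empty list = conformant).

    Checks the closed vocabularies (9 entity types, 7 relation names) and
    that each relation's argument entity types match its signature.
    Structural problems (dangling ids) are also reported rather than raised.
    """
    issues: list[str] = []
    by_id = doc.entity_by_id()
    for e in doc.entities:
        if e.etype not in ENTITY_TYPES:
            issues.append(f"{doc.doc_id}/{e.id}: unknown entity type {e.etype!r}")
    for r in doc.relations:
        sig = RELATION_SIGNATURES.get(r.rtype)
        if sig is None:
            issues.append(f"{doc.doc_id}/{r.id}: unknown relation type {r.rtype!r}")
            continue
        for arg_id, want, slot in ((r.arg1, sig[0], "arg1"), (r.arg2, sig[1], "arg2")):
            ent = by_id.get(arg_id)
            if ent is None:
                issues.append(f"{doc.doc_id}/{r.id}: dangling {slot} {arg_id}")
            elif ent.etype != want:
                issues.append(
                    f"{doc.doc_id}/{r.id}: {slot} of {r.rtype} must be {want}, "
                    f"got {ent.etype}")
    return issues


def read_standoff(text_path: str, ann_path: str) -> Document:
    """Parse a ``.txt`` + ``.ann`` pair into a verified :class:`Document`."""
    with open(text_path, encoding="utf-8") as fh:
        text = fh.read()
    doc_id = os.path.splitext(os.path.basename(text_path))[0]
    entities: list[Entity] = []
    relations: list[Relation] = []
    with open(ann_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            try:
                if line.startswith("T"):
                    ann_id, spec, surface = line.split("\t", 2)
                    etype, start_s, end_s = spec.split(" ")
                    entities.append(Entity(ann_id, etype, int(start_s),
                                           int(end_s), surface))
                elif line.startswith("R"):
                    ann_id, spec = line.split("\t", 1)
                    rtype, a1, a2 = spec.split(" ")
                    if not (a1.startswith("Arg1:") and a2.startswith("Arg2:")):
                        raise ValueError("bad argument slots")
                    relations.append(Relation(ann_id, rtype,
                                              a1[len("Arg1:"):],
                                              a2[len("Arg2:"):]))
                else:
                    raise ValueError("unknown annotation kind")
            except (ValueError, IndexError) as exc:
                raise StandoffParseError(
                    f"{ann_path}:{lineno}: cannot parse {line!r} ({exc})"
                ) from exc
    doc = Document(doc_id=doc_id, text=text, entities=entities,
                   relations=relations)
    doc.check()
    for e in doc.entities:
        if e.etype not in ENTITY_TYPES:
            raise SchemaError(f"{doc_id}/{e.id}: unknown entity type {e.etype!r}")
    for r in doc.relations:
        if r.rtype not in RELATION_SIGNATURES:
            raise SchemaError(f"{doc_id}/{r.id}: unknown relation type {r.rtype!r}")
    return doc


def write_standoff(doc: Document, out_dir: str) -> tuple[str, str]:
    """Write ``<doc_id>.txt`` and ``<doc_id>.ann``; inverse of read_standoff."""
    doc.check()
    os.makedirs(out_dir, exist_ok=True)
    text_path = os.path.join(out_dir, f"{doc.doc_id}.txt")
    ann_path = os.path.join(out_dir, f"{doc.doc_id}.ann")
    with open(text_path, "w", encoding="utf-8") as fh:
        fh.write(doc.text)
    with open(ann_path, "w", encoding="utf-8") as fh:
        for e in doc.entities:
            fh.write(f"{e.id}\t{e.etype} {e.start} {e.end}\t{e.text}\n")
        for r in doc.relations:
            fh.write(f"{r.id}\t{r.rtype} Arg1:{r.arg1} Arg2:{r.arg2}\n")
    return text_path, ann_path


def read_corpus_dir(path: str) -> list[Document]:
    """Read every ``.txt``/``.ann`` basename pair under `path`, sorted."""
    docs = []
    for name in sorted(os.listdir(path)):
        if not name.endswith(".txt"):
            continue
        base = name[:-4]
        ann = os.path.join(path, base + ".ann")
        if not os.path.exists(ann):
            raise FileNotFoundError(f"missing annotation file for {base}")
        docs.append(read_standoff(os.path.join(path, name), ann))
    return docs


def with_annotations(doc: Document, entities: list[Entity] | None = None,
                     relations: list[Relation] | None = None) -> Document:
    """Copy `doc` replacing its annotation layers (used for predictions)."""
    return Document(
        doc_id=doc.doc_id, text=doc.text,
        entities=list(doc.entities) if entities is None else list(entities),
        relations=list(doc.relations) if relations is None else list(relations),
        split=doc.split)
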