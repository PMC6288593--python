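"""Micro-averaged precision/recall/F1 for entities, relations and
end-to-end extraction, with per-type breakdowns.

Matching is exact and unweighted: a predicted entity is a true positive
iff an as-yet-unmatched gold entity has the identical character span and
type; a predicted relation is a true positive iff its type and both
argument entities (span + type) match a gold relation.  Under end-to-end
scoring the predicted arguments come from the tagging stage, so entity
errors propagate into relation errors.  Micro scores are computed from
TP/FP/FN counts summed over all documents (and, for the overall row, over
all types) — not by averaging per-type F1s.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import Document, Entity, Relation

__all__ = ["MatchCounts", "match_entities", "match_relations", "micro_prf",
           "evaluate_documents", "format_report"]


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other: "MatchCounts") -> "MatchCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def _multiset_match(gold_keys: list, pred_keys: list,
                    type_of) -> tuple[MatchCounts, dict[str, MatchCounts]]:
    """Greedy multiset matching on hashable keys; each gold key is consumed
    at most once.  Returns overall and per-type counts."""
    from collections import Counter
    gold_c = Counter(gold_keys)
    overall = MatchCounts()
    per_type: dict[str, MatchCounts] = {}

    def bucket(key) -> MatchCounts:
        return per_type.setdefault(type_of(key), MatchCounts())

    for key in pred_keys:
        if gold_c[key] > 0:
            gold_c[key] -= 1
            overall.tp += 1
            bucket(key).tp += 1
        else:
            overall.fp += 1
            bucket(key).fp += 1
    for key, left in gold_c.items():
        overall.fn += left
        bucket(key).fn += left
    return overall, per_type


def match_entities(gold: list[Entity], pred: list[Entity]
                   ) -> tuple[MatchCounts, dict[str, MatchCounts]]:
    """Exact (start, end, type) matching; each gold matches at most once."""
    key = lambda e: (e.start, e.end, e.etype)
    return _multiset_match([key(e) for e in gold], [key(e) for e in pred],
                           type_of=lambda k: k[2])


def _resolve(relations: list[Relation], doc: Document):
    by_id = doc.entity_by_id()
    keys = []
    for r in relations:
        try:
            a1, a2 = by_id[r.arg1], by_id[r.arg2]
        except KeyError as exc:
            raise KeyError(f"{doc.doc_id}/{r.id}: dangling argument "
                           f"{exc.args[0]}") from exc
        keys.append((r.rtype,
                     (a1.start, a1.end, a1.etype),
                     (a2.start, a2.end, a2.etype)))
    return keys


def match_relations(gold_doc: Document, pred_doc: Document,
                    end_to_end: bool = True
                    ) -> tuple[MatchCounts, dict[str, MatchCounts]]:
    """Relation matching on resolved argument spans.

    `pred_doc` carries the predicted relations and whatever entity layer
    they refer to (predicted entities under end-to-end scoring, gold
    entities otherwise — the flag only documents the provenance; matching
    is identical and entity errors propagate through the resolved spans).
    """
    del end_to_end
    gold_keys = _resolve(gold_doc.relations, gold_doc)
    pred_keys = _resolve(pred_doc.relations, pred_doc)
    return _multiset_match(gold_keys, pred_keys, type_of=lambda k: k[0])


def micro_prf(counts: MatchCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) as fractions in [0, 1]; 0/0 → 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _merge(into: dict[str, MatchCounts], frm: dict[str, MatchCounts]):
    for t, c in frm.items():
        into.setdefault(t, MatchCounts()).__iadd__(c)


def _block(overall: MatchCounts, per_type: dict[str, MatchCounts]) -> dict:
    p, r, f = micro_prf(overall)
    return {
        "counts": {"tp": overall.tp, "fp": overall.fp, "fn": overall.fn},
        "precision": p, "recall": r, "f1": f,
        "per_type": {
            t: dict(zip(("precision", "recall", "f1"), micro_prf(c)),
                    tp=c.tp, fp=c.fp, fn=c.fn)
            for t, c in sorted(per_type.items())},
    }


def evaluate_documents(gold_docs: list[Document], pred_docs: list[Document],
                       end_to_end: bool = True) -> dict:
    """Corpus-level report: entity block and relation block, each with
    overall micro-P/R/F1 and per-type rows recomputed from per-type counts.
    Documents are paired by doc_id."""
    pred_by_id = {d.doc_id: d for d in pred_docs}
    ent_all, rel_all = MatchCounts(), MatchCounts()
    ent_types: dict[str, MatchCounts] = {}
    rel_types: dict[str, MatchCounts] = {}
    for gold in gold_docs:
        pred = pred_by_id.get(gold.doc_id)
        if pred is None:
            pred = Document(doc_id=gold.doc_id, text=gold.text)
        eo, et = match_entities(gold.entities, pred.entities)
        ro, rt = match_relations(gold, pred, end_to_end=end_to_end)
        ent_all += eo
        rel_all += ro
        _merge(ent_types, et)
        _merge(rel_types, rt)
    return {"matching": "exact-span",
            "end_to_end": end_to_end,
            "entity": _block(ent_all, ent_types),
            "relation": _block(rel_all, rel_types)}


def format_report(report: dict) -> str:
    """Text tables mirroring the usual per-type P/R/F1 layout (percent)."""
    lines = [f"matching: {report['matching']}   "
             f"end_to_end: {report['end_to_end']}"]
    for block_name in ("entity", "relation"):
        block = report[block_name]
        lines.append(f"\n[{block_name}]  "
                     f"tp={block['counts']['tp']} fp={block['counts']['fp']} "
                     f"fn={block['counts']['fn']}")
        lines.append(f"{'type':<24}{'P':>8}{'R':>8}{'F1':>8}")
        for t, row in block["per_type"].items():
            lines.append(f"{t:<24}{100 * row['precision']:>8.1f}"
                         f"{100 * row['recall']:>8.1f}{100 * row['f1']:>8.1f}")
        lines.append(f"{'micro (overall)':<24}{100 * block['precision']:>8.1f}"
                     f"{100 * block['recall']:>8.1f}{100 * block['f1']:>8.1f}")
    return "\n".join(lines)
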