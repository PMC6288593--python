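"""Micro-averaged scoring arithmetic and matching semantics."""

from itertools import permutations

import pytest

from adex.corpus import Document, Entity, Relation
from adex.evaluation import (MatchCounts, evaluate_documents, format_report,
                             match_entities, match_relations, micro_prf)


# --------------------------------------------------------- micro_prf table

@pytest.mark.parametrize("tp,fp,fn,want", [
    (3, 1, 2, (0.75, 0.6, 2 * 0.75 * 0.6 / 1.35)),
    (0, 0, 0, (0.0, 0.0, 0.0)),            # 0/0 convention
    (0, 5, 0, (0.0, 0.0, 0.0)),
    (0, 0, 5, (0.0, 0.0, 0.0)),
    (10, 0, 0, (1.0, 1.0, 1.0)),
    (1, 1, 1, (0.5, 0.5, 0.5)),
    (7, 3, 0, (0.7, 1.0, 2 * 0.7 / 1.7)),
    (2, 0, 6, (1.0, 0.25, 0.4)),
    (50, 25, 25, (2 / 3, 2 / 3, 2 / 3)),
    (1, 9, 9, (0.1, 0.1, 0.1)),
    (4, 2, 8, (4 / 6, 4 / 12, 2 * (4 / 6) * (1 / 3) / (4 / 6 + 1 / 3))),
])
def test_micro_prf_hand_computed(tp, fp, fn, want):
    got = micro_prf(MatchCounts(tp, fp, fn))
    assert got == pytest.approx(want, abs=1e-12)


def test_micro_f1_is_not_mean_of_per_type_f1s():
    # rare type A is perfect (F1=1), frequent type B is mediocre (F1=.5):
    # micro-F1 pools the counts and sits near B, far from the macro mean
    a = MatchCounts(1, 0, 0)
    b = MatchCounts(10, 10, 10)
    micro = micro_prf(MatchCounts(11, 10, 10))[2]
    macro = (micro_prf(a)[2] + micro_prf(b)[2]) / 2
    assert micro == pytest.approx(11 / 21)
    assert macro == pytest.approx(0.75)
    assert abs(micro - macro) > 0.2  # the two aggregations disagree


# -------------------------------------------------------- entity matching

def E(i, t, s, e):
    return Entity(f"T{i}", t, s, e, "x" * (e - s))


def test_identical_lists_are_perfect():
    gold = [E(1, "ADE", 0, 4), E(2, "Medication", 5, 9)]
    overall, _ = match_entities(gold, list(gold))
    assert (overall.tp, overall.fp, overall.fn) == (2, 0, 0)


def test_off_by_one_span_counts_fp_and_fn():
    overall, per_type = match_entities([E(1, "ADE", 0, 4)],
                                       [E(1, "ADE", 0, 5)])
    assert (overall.tp, overall.fp, overall.fn) == (0, 1, 1)
    assert per_type["ADE"].fp == 1 and per_type["ADE"].fn == 1


def test_each_gold_matches_at_most_once():
    gold = [E(1, "ADE", 0, 4)]
    pred = [E(1, "ADE", 0, 4), E(2, "ADE", 0, 4)]
    overall, _ = match_entities(gold, pred)
    assert (overall.tp, overall.fp, overall.fn) == (1, 1, 0)


def test_swapping_gold_and_pred_swaps_p_and_r():
    gold = [E(1, "ADE", 0, 4), E(2, "ADE", 8, 12), E(3, "SSLIF", 20, 24)]
    pred = [E(1, "ADE", 0, 4), E(2, "SSLIF", 30, 34)]
    p1, r1, f1 = micro_prf(match_entities(gold, pred)[0])
    p2, r2, f2 = micro_prf(match_entities(pred, gold)[0])
    assert (p1, r1) == (r2, p2) and f1 == pytest.approx(f2)


def test_matching_agrees_with_bipartite_oracle():
    """Greedy multiset matching equals the optimal assignment for exact
    keys: maximum matching size = sum of min(count_gold, count_pred)."""
    import numpy as np
    from collections import Counter
    rng = np.random.default_rng(5)
    for _ in range(50):
        keys = [(0, 4, "ADE"), (5, 9, "ADE"), (5, 9, "SSLIF"), (0, 4, "SSLIF")]
        gold = [keys[i] for i in rng.integers(0, 4, rng.integers(0, 6))]
        pred = [keys[i] for i in rng.integers(0, 4, rng.integers(0, 6))]
        overall, _ = match_entities(
            [Entity(f"G{i}", k[2], k[0], k[1], "xxxx")
             for i, k in enumerate(gold)],
            [Entity(f"P{i}", k[2], k[0], k[1], "xxxx")
             for i, k in enumerate(pred)])
        gc, pc = Counter(gold), Counter(pred)
        best = sum(min(gc[k], pc[k]) for k in gc)
        assert overall.tp == best
        assert overall.fp == len(pred) - best
        assert overall.fn == len(gold) - best


# ------------------------------------------------------ relation matching

def _rel_doc(entities, relations):
    return Document(doc_id="d", text="x" * 100, entities=entities,
                    relations=relations)


def test_perfect_relations_score_one():
    ents = [E(1, "Severity", 0, 4), E(2, "ADE", 5, 9)]
    gold = _rel_doc(ents, [Relation("R1", "Severity-ADE", "T1", "T2")])
    pred = _rel_doc(list(ents), [Relation("R9", "Severity-ADE", "T1", "T2")])
    overall, _ = match_relations(gold, pred)
    assert micro_prf(overall) == (1.0, 1.0, 1.0)


def test_wrong_argument_span_propagates_to_fp_and_fn():
    gold = _rel_doc([E(1, "Severity", 0, 4), E(2, "ADE", 5, 9)],
                    [Relation("R1", "Severity-ADE", "T1", "T2")])
    pred = _rel_doc([E(1, "Severity", 0, 4), E(2, "ADE", 5, 10)],
                    [Relation("R1", "Severity-ADE", "T1", "T2")])
    overall, _ = match_relations(gold, pred)
    assert (overall.tp, overall.fp, overall.fn) == (0, 1, 1)


def test_dangling_argument_raises():
    gold = _rel_doc([E(1, "Severity", 0, 4), E(2, "ADE", 5, 9)], [])
    pred = _rel_doc([E(1, "Severity", 0, 4)],
                    [Relation("R1", "Severity-ADE", "T1", "T99")])
    with pytest.raises(KeyError, match="T99"):
        match_relations(gold, pred)


def test_relation_matching_agrees_with_exhaustive_comparison():
    """On documents with <= 4 relations, counts equal the best one-to-one
    pairing found by exhaustive permutation search."""
    ents = [E(1, "Medication", 0, 4), E(2, "ADE", 5, 9),
            E(3, "ADE", 10, 14), E(4, "Severity", 15, 19)]
    gold = _rel_doc(ents, [Relation("R1", "Medication-ADE", "T1", "T2"),
                           Relation("R2", "Medication-ADE", "T1", "T3"),
                           Relation("R3", "Severity-ADE", "T4", "T3")])
    pred = _rel_doc(list(ents),
                    [Relation("P1", "Medication-ADE", "T1", "T2"),
                     Relation("P2", "Severity-ADE", "T4", "T2"),
                     Relation("P3", "Severity-ADE", "T4", "T3")])
    overall, _ = match_relations(gold, pred)

    def key(doc, r):
        by = doc.entity_by_id()
        a, b = by[r.arg1], by[r.arg2]
        return (r.rtype, (a.start, a.end, a.etype), (b.start, b.end, b.etype))

    gk = [key(gold, r) for r in gold.relations]
    pk = [key(pred, r) for r in pred.relations]
    best = 0
    for perm in permutations(range(len(pk))):
        tp = sum(1 for i, j in zip(range(len(gk)), perm)
                 if i < len(gk) and j < len(pk) and gk[i] == pk[j])
        best = max(best, tp)
    assert overall.tp == best == 2


# ------------------------------------------------------------- reporting

def test_per_type_counts_sum_to_overall(small_corpus):
    docs = small_corpus.train[:10]
    # score the corpus against a shifted copy of itself
    preds = [Document(doc_id=d.doc_id, text=d.text,
                      entities=d.entities[:-1] if d.entities else [],
                      relations=d.relations[:-1] if d.relations else [])
             for d in docs]
    report = evaluate_documents(docs, preds)
    for block in (report["entity"], report["relation"]):
        for f in ("tp", "fp", "fn"):
            assert block["counts"][f] == sum(row[f]
                                             for row in block["per_type"]
                                             .values())
    text = format_report(report)
    assert "micro (overall)" in text


def test_missing_predicted_document_counts_as_all_fn(small_corpus):
    docs = small_corpus.train[:2]
    report = evaluate_documents(docs, [])
    assert report["entity"]["counts"]["tp"] == 0
    assert report["entity"]["counts"]["fn"] == \
        sum(len(d.entities) for d in docs)
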