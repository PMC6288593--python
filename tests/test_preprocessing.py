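"""Tokenization, POS tagging, BMES coding and relation candidates."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from adex.corpus import Document, Entity, Relation
from adex.preprocessing import (LABELS, OverlapError, align_entity,
                                bucket_distance, build_relation_candidates,
                                compute_positions, decode_bmes, encode_bmes,
                                pos_tag, tokenize_and_split)


# ----------------------------------------------------------- tokenization

def test_label_alphabet_size():
    assert len(LABELS) == 4 * 9 + 1


def test_tokenize_offsets_and_capital_flags():
    sents = tokenize_and_split("Renal Failure.")
    assert [t.text for t in sents[0]] == ["Renal", "Failure", "."]
    assert [t.initial_capital for t in sents[0]] == [True, True, False]


def test_tokenize_empty_text_gives_empty_list():
    assert tokenize_and_split("") == []


def test_sentence_split_on_terminator_and_newline():
    sents = tokenize_and_split("one . two .\nthree")
    assert len(sents) == 3
    assert [t.text for t in sents[2]] == ["three"]


@settings(derandomize=True, max_examples=60)
@given(st.text(alphabet=st.characters(codec="ascii"), max_size=120))
def test_token_offsets_round_trip(text):
    for sent in tokenize_and_split(text):
        for tok in sent:
            assert text[tok.start:tok.end] == tok.text


# --------------------------------------------------------------- POS tags

def test_pos_tagger_examples_and_determinism():
    sent = tokenize_and_split("Renal biopsy showed 50 lesions .")[0]
    pos_tag(sent)
    tags = [t.pos for t in sent]
    assert tags[0] == "JJ"        # -al adjective suffix
    assert tags[3] == "CD"        # numeral
    assert tags[-1] == "."
    again = tokenize_and_split("Renal biopsy showed 50 lesions .")[0]
    pos_tag(again)
    assert [t.pos for t in again] == tags


# ------------------------------------------------------------ BMES coding

def _sent(text):
    return tokenize_and_split(text)[0]


def test_encode_two_token_entity():
    sent = _sent("Renal Failure today")
    labels = encode_bmes(sent, [Entity("T1", "SSLIF", 0, 13, "Renal Failure")])
    assert labels == ["B_SSLIF", "E_SSLIF", "O"]


def test_encode_single_token_entity():
    sent = _sent("started antibiotics now")
    labels = encode_bmes(sent, [Entity("T1", "Medication", 8, 19,
                                       "antibiotics")])
    assert labels == ["O", "S_Medication", "O"]


def test_encode_overlapping_entities_raise():
    sent = _sent("renal failure")
    with pytest.raises(OverlapError, match="T1.*T2|T2.*T1"):
        encode_bmes(sent, [Entity("T1", "SSLIF", 0, 13, "renal failure"),
                           Entity("T2", "ADE", 6, 13, "failure")])


def test_misaligned_span_snaps_outward_and_reports():
    sent = _sent("taking megadrugs daily")
    report = []
    labels = encode_bmes(sent, [Entity("T1", "Medication", 7, 11, "mega")],
                         snap_report=report)
    assert labels[1] == "S_Medication"
    assert report and report[0][2] == (7, 16)


def test_encode_decode_inverse_on_aligned_entities():
    sent = _sent("mild nausea after megadrug therapy")
    ents = [Entity("T1", "Severity", 0, 4, "mild"),
            Entity("T2", "ADE", 5, 11, "nausea"),
            Entity("T3", "Medication", 18, 26, "megadrug")]
    decoded = decode_bmes(encode_bmes(sent, ents), sent)
    assert [(e.start, e.end, e.etype) for e in decoded] == \
        [(e.start, e.end, e.etype) for e in ents]


def _regex_reference_decode(labels):
    """Independent decode oracle: per-type regex over the label string,
    preferring S, then a closed B·M*·E run, then an unclosed B·M* run."""
    spans = []
    types = {lab[2:] for lab in labels if lab != "O"}
    for t in sorted(types):
        code = "".join(lab[0] if lab != "O" and lab[2:] == t else "O"
                       for lab in labels)
        for m in re.finditer(r"S|BM*E|BM*", code):
            spans.append((m.start(), m.end() - 1, t))
    return sorted(spans)


@pytest.mark.parametrize("labels,expected", [
    (["O", "M_ADE", "O"], []),
    (["E_ADE"], []),
    (["B_ADE"], [(0, 0, "ADE")]),
    (["B_ADE", "E_ADE"], [(0, 1, "ADE")]),
    (["B_ADE", "M_ADE", "O"], [(0, 1, "ADE")]),
    (["B_ADE", "M_ADE", "M_ADE", "E_ADE"], [(0, 3, "ADE")]),
    (["S_ADE", "S_SSLIF"], [(0, 0, "ADE"), (1, 1, "SSLIF")]),
    (["B_ADE", "E_SSLIF"], [(0, 0, "ADE")]),
    (["B_ADE", "M_SSLIF", "E_ADE"], [(0, 0, "ADE")]),
    (["O", "B_ADE", "M_ADE"], [(1, 2, "ADE")]),
])
def test_repair_rule_hand_table(labels, expected):
    sent = _sent(" ".join("tok" for _ in labels))
    decoded = decode_bmes(labels, sent)
    spans = sorted((align_entity(e, sent)[0], align_entity(e, sent)[1],
                    e.etype) for e in decoded)
    assert spans == expected


def test_repair_rule_matches_regex_oracle_exhaustively():
    """All label patterns of length <= 4 over two entity types."""
    alphabet = ["O"] + [f"{p}_{t}" for t in ("ADE", "SSLIF") for p in "BMES"]
    from itertools import product
    for n in range(1, 5):
        sent = _sent(" ".join("tok" for _ in range(n)))
        for labels in product(alphabet, repeat=n):
            decoded = decode_bmes(list(labels), sent)
            got = sorted((align_entity(e, sent)[0],
                          align_entity(e, sent)[1], e.etype)
                         for e in decoded)
            assert got == _regex_reference_decode(list(labels)), labels


# -------------------------------------------------- candidates & positions

def _doc(text, entities, relations=()):
    return Document(doc_id="d", text=text, entities=list(entities),
                    relations=list(relations))


def test_candidate_for_gold_pair_carries_label():
    text = "started megadrug 50 mg .\n"
    doc = _doc(text, [Entity("T1", "Medication", 8, 16, "megadrug"),
                      Entity("T2", "Dosage", 17, 22, "50 mg")],
               [Relation("R1", "Dosage-Medication", "T2", "T1")])
    sents = tokenize_and_split(text)
    cands = build_relation_candidates(doc, sents, max_sentence_gap=3)
    assert len(cands) == 1
    assert cands[0].label == "Dosage-Medication"
    assert (cands[0].arg1_id, cands[0].arg2_id) == ("T2", "T1")


def test_type_incompatible_pair_yields_no_candidate():
    text = "megadrug with fatigue .\n"
    doc = _doc(text, [Entity("T1", "Medication", 0, 8, "megadrug"),
                      Entity("T2", "SSLIF", 14, 21, "fatigue")])
    cands = build_relation_candidates(doc, tokenize_and_split(text), 3)
    assert cands == []


def test_two_by_two_pairs_enumerate_four_candidates():
    text = "druga drugb caused rash and hives .\n"
    doc = _doc(text, [Entity("T1", "Medication", 0, 5, "druga"),
                      Entity("T2", "Medication", 6, 11, "drugb"),
                      Entity("T3", "ADE", 19, 23, "rash"),
                      Entity("T4", "ADE", 28, 33, "hives")])
    cands = build_relation_candidates(doc, tokenize_and_split(text), 3)
    assert len(cands) == 4  # brute-force pair enumeration: 2 x 2


def test_sentence_gap_limit_excludes_distant_pairs():
    text = "megadrug given .\nfine .\nfine .\nrash noted .\n"
    doc = _doc(text, [Entity("T1", "Medication", 0, 8, "megadrug"),
                      Entity("T2", "ADE", 31, 35, "rash")])
    sents = tokenize_and_split(text)
    assert build_relation_candidates(doc, sents, max_sentence_gap=2) == []
    far = build_relation_candidates(doc, sents, max_sentence_gap=3)
    assert len(far) == 1
    assert far[0].sentence_gap == 3
    # window spans from first token of the earlier sentence to the last
    # token of the later sentence
    assert far[0].window[0].text == "megadrug"
    assert far[0].window[-1].text == "."


def test_candidate_generation_complete_on_synthetic_docs(small_corpus):
    for doc in small_corpus.train:
        sents = tokenize_and_split(doc.text)
        cands = build_relation_candidates(doc, sents, max_sentence_gap=3)
        labelled = {(c.arg1_id, c.arg2_id): c.label for c in cands}
        for r in doc.relations:
            assert labelled.get((r.arg1, r.arg2)) == r.rtype


def test_positions_convention_and_arithmetic():
    # entity1 ends at index 4, entity2 starts at index 8; token at index 6
    pos1 = compute_positions(12, (3, 4))
    pos2 = compute_positions(12, (8, 9))
    assert pos1[2] == -1 and pos1[3] == 0 and pos1[4] == 0
    assert (pos1[6], pos2[6]) == (2, -2)
    assert pos2[11] == 2


def test_distance_buckets():
    assert [bucket_distance(d) for d in (0, 1, 2, 4, 7, 11, 100)] == \
        [0, 1, 2, 3, 4, 5, 5]
    with pytest.raises(ValueError):
        bucket_distance(-1)
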