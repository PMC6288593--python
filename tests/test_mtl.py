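"""Coupling contracts of the multi-task systems: gradient partition under
hard sharing, the regularization penalty's closed forms and its exact
λ=0 degeneration to the pipeline, and the zero-exchange degeneration of
task-relation learning."""

import json

import numpy as np
import pytest

from adex._autograd import Parameter, Tensor, concat
from adex.mtl import (ExtractionSystem, HardMTL, LearnMTL, RegMTL,
                      evaluate_system, regmtl_penalty, train_multitask)
from adex.ner import NerConfig, prepare_ner_data
from adex.nn import Adam
from adex.relation import ReConfig, prepare_re_data

NER_CFG = NerConfig(word_dim=8, char_dim=4, char_cnn_filters=6, pos_dim=4,
                    capital_dim=2, lstm_hidden=6, dropout=0.0, seed=21)
RE_CFG = ReConfig(word_dim=8, pos_dim=4, position_dim=4, lstm_hidden=6,
                  attention_dim=5, type_dim=3, bucket_dim=3, dropout=0.0,
                  seed=21)


def _built(cls, docs, **kw):
    system = cls(NER_CFG, RE_CFG, **kw)
    system.fit(docs, epochs=0)
    return system


def _batches(system, docs):
    ner_data = prepare_ner_data(docs)
    insts = prepare_re_data(docs, system.re.config.max_sentence_gap)
    bn = system.ner.featurize([s for s, _ in ner_data[:6]],
                              [l for _, l in ner_data[:6]])
    br = system.re.featurize(insts[:6])
    return bn, br


# ------------------------------------------------------------ regmtl_penalty

def test_penalty_zero_for_tied_parameters():
    p = [Parameter(np.ones((3, 4))), Parameter(np.zeros(5))]
    q = [Parameter(np.ones((3, 4))), Parameter(np.zeros(5))]
    assert regmtl_penalty(p, q, 1.0).item() == 0.0


def test_penalty_closed_form_unit_offset():
    k = 3 * 4 + 5
    p = [Parameter(np.ones((3, 4))), Parameter(np.ones(5))]
    q = [Parameter(np.zeros((3, 4))), Parameter(np.zeros(5))]
    assert regmtl_penalty(p, q, 1.0).item() == pytest.approx(k)
    assert regmtl_penalty(p, q, 0.5).item() == pytest.approx(0.5 * k)


def test_penalty_shape_mismatch_raises():
    with pytest.raises(ValueError):
        regmtl_penalty([Parameter(np.ones(3))], [Parameter(np.ones(4))], 1.0)


def test_penalty_gradient_contracts_parameter_distance():
    rng = np.random.default_rng(0)
    p = [Parameter(rng.normal(size=(4, 4)))]
    q = [Parameter(rng.normal(size=(4, 4)))]
    opt = Adam([*p, *q], lr=0.05)
    d0 = float(np.abs(p[0].data - q[0].data).sum())
    for _ in range(60):
        for t in (*p, *q):
            t.grad = None
        regmtl_penalty(p, q, 1.0).backward()
        opt.step()
    d1 = float(np.abs(p[0].data - q[0].data).sum())
    assert d1 < 0.1 * d0


# ------------------------------------------------------- hard-sharing MTL

def test_hard_ner_step_spares_re_private_parameters(tiny_docs):
    system = _built(HardMTL, tiny_docs)
    bn, _ = _batches(system, tiny_docs)
    before_re = {k: v.copy() for k, v in system.re.state_dict().items()}
    before_sh = system.shared_lstm.state_dict()
    before_ner = system.ner.state_dict()
    opt = Adam(system.trainable_parameters(), lr=1e-2)
    system.zero_grad()
    system.loss_ner(bn).backward()
    opt.step()
    after_re = system.re.state_dict()
    for k in before_re:  # bitwise untouched
        np.testing.assert_array_equal(before_re[k], after_re[k])
    assert any(not np.array_equal(before_sh[k], v)
               for k, v in system.shared_lstm.state_dict().items())
    assert any(not np.array_equal(before_ner[k], v)
               for k, v in system.ner.state_dict().items())


def test_hard_re_step_spares_ner_private_lstm(tiny_docs):
    system = _built(HardMTL, tiny_docs)
    _, br = _batches(system, tiny_docs)
    before_ner_lstm = system.ner.lstms[0].state_dict()
    before_sh = system.shared_lstm.state_dict()
    opt = Adam(system.trainable_parameters(), lr=1e-2)
    system.zero_grad()
    system.loss_re(br).backward()
    opt.step()
    for k, v in system.ner.lstms[0].state_dict().items():
        np.testing.assert_array_equal(before_ner_lstm[k], v)
    assert any(not np.array_equal(before_sh[k], v)
               for k, v in system.shared_lstm.state_dict().items())


def test_hard_zeroing_shared_layer_changes_both_tasks(tiny_docs):
    system = _built(HardMTL, tiny_docs)
    bn, br = _batches(system, tiny_docs)
    e0 = system.ner.encode(bn).data.copy()
    l0 = system.re.logits(br).data.copy()
    for p in system.shared_lstm.parameters():
        p.data[:] = 0.0
    assert not np.allclose(e0, system.ner.encode(bn).data)
    assert not np.allclose(l0, system.re.logits(br).data)


# -------------------------------------------------------------- reg MTL

def test_reg_requires_two_layers():
    with pytest.raises(ValueError, match="two stacked"):
        RegMTL(NER_CFG, RE_CFG)


def test_reg_lambda_zero_reproduces_pipeline_exactly(tiny_docs):
    from dataclasses import replace
    ncfg = replace(NER_CFG, lstm_layers=2)
    rcfg = replace(RE_CFG, lstm_layers=2)
    pipe = ExtractionSystem(ncfg, rcfg)
    log_p = pipe.fit(tiny_docs, epochs=2)
    reg = RegMTL(ncfg, rcfg, lambda_reg=0.0)
    log_r = reg.fit(tiny_docs, epochs=2)
    for a, b in zip(log_p, log_r):
        assert a["ner_loss"] == b["ner_loss"]
        assert a["re_loss"] == b["re_loss"]
    sp, sr = pipe.state_dict(), reg.state_dict()
    assert set(sp) == set(sr)
    for k in sp:
        np.testing.assert_array_equal(sp[k], sr[k])


def test_reg_large_lambda_contracts_second_layers(tiny_docs):
    from dataclasses import replace
    ncfg = replace(NER_CFG, lstm_layers=2)
    rcfg = replace(RE_CFG, lstm_layers=2)

    def distance_after(lam):
        system = RegMTL(ncfg, rcfg, lambda_reg=lam)
        system.fit(tiny_docs, epochs=2)
        p, q = system.second_layer_params()
        return sum(float(np.abs(a.data - b.data).sum()) for a, b in
                   zip(p, q))

    d = [distance_after(lam) for lam in (0.0, 0.1, 10.0)]
    assert d[2] < d[1] < d[0]


# ------------------------------------------------------------- learn MTL

def test_learn_zero_exchange_matches_widened_baseline(tiny_docs):
    system = _built(LearnMTL, tiny_docs)
    bn, br = _batches(system, tiny_docs)
    for p in (*system.W5_re_to_ner.parameters(),
              *system.W5_ner_to_re.parameters()):
        p.data[:] = 0.0
    # tagger: emissions equal proj([private hidden ; zeros])
    h = system.ner.hidden(bn)
    B, T = bn["mask"].shape
    zeros = Tensor(np.zeros((B, T, system.exchange_dim)))
    want = system.ner.proj(concat([h, zeros], axis=2)).data
    np.testing.assert_allclose(system.ner.encode(bn).data, want, atol=1e-12)
    # classifier: logits equal out([ctx ; zeros ; side])
    from adex.relation import attention_pool
    hr = system.re.encode(br)
    ctx, _ = attention_pool(hr, system.re.att_W, system.re.att_v, br["mask"])
    zeros = Tensor(np.zeros((ctx.shape[0], system.exchange_dim)))
    want = system.re.out(concat([ctx, zeros,
                                 system.re.side_features(br)], axis=1)).data
    np.testing.assert_allclose(system.re.logits(br).data, want, atol=1e-12)


def test_learn_exchange_perturbation_moves_both_decoders(tiny_docs):
    system = _built(LearnMTL, tiny_docs)
    bn, br = _batches(system, tiny_docs)
    e0 = system.ner.encode(bn).data.copy()
    l0 = system.re.logits(br).data.copy()
    system.W5_re_to_ner.W.data += 0.5
    system.W5_ner_to_re.W.data += 0.5
    assert not np.allclose(e0, system.ner.encode(bn).data)
    assert not np.allclose(l0, system.re.logits(br).data)


def test_learn_decoder_width_contract(tiny_docs):
    system = _built(LearnMTL, tiny_docs)
    assert system.ner.proj.W.shape[0] == \
        2 * system.ner.config.lstm_hidden + system.exchange_dim


# -------------------------------------------------------------- trainer

def test_train_multitask_rejects_bad_inputs(tiny_docs):
    with pytest.raises(ValueError, match="unknown mode"):
        train_multitask("bogus", tiny_docs)
    with pytest.raises(ValueError, match="empty"):
        ExtractionSystem(NER_CFG, RE_CFG).fit([])


def test_joint_loss_decreases_in_hard_mode(tiny_docs):
    system, log = train_multitask("hard", tiny_docs, NER_CFG, RE_CFG,
                                  epochs=6)
    first = log[0]["ner_loss"] + log[0]["re_loss"]
    last = log[-1]["ner_loss"] + log[-1]["re_loss"]
    assert last < 0.7 * first


def test_all_modes_emit_schema_valid_predictions(small_corpus):
    from adex.corpus import validate_schema
    for mode in ("pipeline", "hard", "reg", "learn"):
        system, _ = train_multitask(mode, small_corpus.train[:10],
                                    NER_CFG, RE_CFG, epochs=1)
        for doc in small_corpus.test[:3]:
            pred = system.predict_document(doc)
            assert validate_schema(pred) == []


def test_save_load_round_trip(tmp_path, tiny_docs):
    system, _ = train_multitask("hard", tiny_docs, NER_CFG, RE_CFG, epochs=1)
    system.save(str(tmp_path / "m"))
    back = ExtractionSystem.load(str(tmp_path / "m"))
    assert isinstance(back, HardMTL)
    doc = tiny_docs[0]
    a = system.predict_document(doc)
    b = back.predict_document(doc)
    assert json.dumps([(e.start, e.end, e.etype) for e in a.entities]) == \
        json.dumps([(e.start, e.end, e.etype) for e in b.entities])
    assert [(r.rtype, r.arg1, r.arg2) for r in a.relations] == \
        [(r.rtype, r.arg1, r.arg2) for r in b.relations]
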