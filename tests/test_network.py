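"""LSTM cell, BiLSTM, projection and CRF against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trigrec import _autodiff as ad
from trigrec import network
from trigrec.config import TrainConfig
from trigrec.corpus_io import LabelSet
from trigrec.errors import ConfigError
from trigrec.features import FeatureConfig
from trigrec.models import TriggerModel, train_basic
from trigrec.network import (ParameterBundle, bilstm_forward, crf_forward_np,
                             crf_log_likelihood, crf_path_score, crf_viterbi,
                             fc_project, lstm_step_np)


def _cell(rng, d, h, scale=1.0):
    return {"W_x": rng.normal(size=(d, 4 * h)) * scale,
            "W_h": rng.normal(size=(h, 4 * h)) * scale,
            "p_i": rng.normal(size=h) * scale, "p_f": rng.normal(size=h) * scale,
            "p_o": rng.normal(size=h) * scale, "b": rng.normal(size=4 * h) * scale}


def _zero_cell(d, h):
    return {k: np.zeros_like(v) for k, v in _cell(np.random.default_rng(0), d, h).items()}


class TestLSTMStep:
    def test_zero_parameters_zero_state(self):
        p = _zero_cell(3, 2)
        h, c = lstm_step_np(np.array([1.0, -2.0, 0.5]), np.zeros(2), np.zeros(2), p)
        # sigma(0) = 0.5 gates, tanh(0) = 0 candidate -> c = h = 0
        assert np.array_equal(h, np.zeros(2)) and np.array_equal(c, np.zeros(2))

    def test_scalar_oracle(self):
        """Hidden size 1: compare against a literal step-by-step evaluation
        of the peephole equations coded independently."""
        wxi, wxf, wxg, wxo = 0.3, -0.2, 0.7, 0.1
        whi, whf, whg, who = -0.4, 0.5, 0.2, -0.6
        wci, wcf, wco = 0.25, -0.15, 0.35
        bi, bf, bg, bo = 0.05, -0.1, 0.2, 0.0
        x, h0, c0 = 0.8, -0.3, 0.6

        sig = lambda v: 1.0 / (1.0 + math.exp(-v))
        i = sig(wxi * x + whi * h0 + wci * c0 + bi)
        f = sig(wxf * x + whf * h0 + wcf * c0 + bf)
        c = f * c0 + i * math.tanh(wxg * x + whg * h0 + bg)
        o = sig(wxo * x + who * h0 + wco * c + bo)
        h = o * math.tanh(c)

        p = {"W_x": np.array([[wxi, wxf, wxg, wxo]]),
             "W_h": np.array([[whi, whf, whg, who]]),
             "p_i": np.array([wci]), "p_f": np.array([wcf]),
             "p_o": np.array([wco]), "b": np.array([bi, bf, bg, bo])}
        h_got, c_got = lstm_step_np(np.array([x]), np.array([h0]), np.array([c0]), p)
        assert h_got[0] == pytest.approx(h, abs=1e-12)
        assert c_got[0] == pytest.approx(c, abs=1e-12)

    def test_peephole_switch_changes_result(self, rng):
        p = _cell(rng, 2, 3)
        x, h0, c0 = rng.normal(size=2), rng.normal(size=3), rng.normal(size=3)
        with_peep, _ = lstm_step_np(x, h0, c0, p, peephole=True)
        without, _ = lstm_step_np(x, h0, c0, p, peephole=False)
        assert not np.allclose(with_peep, without)

    def test_hidden_state_bounded(self, rng):
        p = _cell(rng, 2, 3, scale=4.0)
        h = np.zeros(3)
        c = np.zeros(3)
        for _ in range(10):
            h, c = lstm_step_np(rng.normal(size=2) * 5, h, c, p)
            assert np.all(np.abs(h) < 1.0)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ConfigError):
            lstm_step_np(np.zeros(5), np.zeros(3), np.zeros(3), _cell(rng, 2, 3))


class TestBiLSTM:
    def test_length_one_equals_single_steps(self, rng):
        fwd, bwd = _cell(rng, 3, 2), _cell(rng, 3, 2)
        x = rng.normal(size=(1, 3))
        out = bilstm_forward(x, fwd, bwd, 2).data
        hf, _ = lstm_step_np(x[0], np.zeros(2), np.zeros(2), fwd)
        hb, _ = lstm_step_np(x[0], np.zeros(2), np.zeros(2), bwd)
        assert np.allclose(out[0], np.concatenate([hf, hb]), atol=1e-12)

    def test_reversal_swaps_and_reverses_halves(self, rng):
        fwd, bwd = _cell(rng, 3, 2), _cell(rng, 3, 2)
        X = rng.normal(size=(5, 3))
        out = bilstm_forward(X, fwd, bwd, 2).data
        rev = bilstm_forward(X[::-1], bwd, fwd, 2).data
        assert np.allclose(out[:, :2], rev[::-1, 2:], atol=1e-12)
        assert np.allclose(out[:, 2:], rev[::-1, :2], atol=1e-12)

    def test_zero_parameters_zero_output(self):
        out = bilstm_forward(np.ones((4, 3)), _zero_cell(3, 2), _zero_cell(3, 2), 2)
        assert np.array_equal(out.data, np.zeros((4, 4)))

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ConfigError):
            bilstm_forward(np.zeros((0, 3)), _cell(rng, 3, 2), _cell(rng, 3, 2), 2)

    def test_causality_of_directions(self, rng):
        """Perturbing position t changes the forward half only at >= t and
        the backward half only at <= t."""
        fwd, bwd = _cell(rng, 3, 2), _cell(rng, 3, 2)
        X = rng.normal(size=(5, 3))
        base = bilstm_forward(X, fwd, bwd, 2).data
        X2 = X.copy()
        X2[2] += 1.0
        pert = bilstm_forward(X2, fwd, bwd, 2).data
        assert np.allclose(base[:2, :2], pert[:2, :2])      # fwd unaffected before t
        assert np.allclose(base[3:, 2:], pert[3:, 2:])      # bwd unaffected after t


class TestFCProject:
    def test_relu_definition(self):
        fc = {"W": np.eye(2), "b": np.zeros(2)}
        proj = {"W": np.eye(2), "b": np.zeros(2)}
        out = fc_project(np.array([[-1.0, 2.0]]), fc, proj)
        assert np.array_equal(out.data, [[0.0, 2.0]])

    def test_zero_input_zero_hidden(self):
        fc = {"W": np.ones((3, 4)), "b": np.zeros(4)}
        proj = {"W": np.ones((4, 2)), "b": np.zeros(2)}
        assert np.array_equal(fc_project(np.zeros((2, 3)), fc, proj).data,
                              np.zeros((2, 2)))

    def test_random_params_match_direct_evaluation(self, rng):
        H = rng.normal(size=(4, 3))
        fc = {"W": rng.normal(size=(3, 5)), "b": rng.normal(size=5)}
        proj = {"W": rng.normal(size=(5, 2)), "b": rng.normal(size=2)}
        expected = np.maximum(0.0, H @ fc["W"] + fc["b"]) @ proj["W"] + proj["b"]
        assert np.allclose(fc_project(H, fc, proj).data, expected, atol=1e-12)


def _enumerate_paths(emissions, trans):
    T, L = emissions.shape
    START, STOP = L, L + 1
    for path in itertools.product(range(L), repeat=T):
        s = trans[START, path[0]] + trans[path[-1], STOP]
        s += sum(emissions[t, path[t]] for t in range(T))
        s += sum(trans[path[t], path[t + 1]] for t in range(T - 1))
        yield s, path


class TestCRF:
    def test_uniform_loglik_is_minus_T_log_L(self):
        T, L = 2, 3
        llh = crf_log_likelihood(np.zeros((T, L)), [0, 2],
                                 np.zeros((L + 2, L + 2)))
        assert float(llh.data) == pytest.approx(-T * np.log(L), abs=1e-12)

    @given(st.integers(1, 5), st.integers(2, 4), st.integers(0, 10_000))
    def test_forward_matches_enumeration(self, T, L, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=(T, L)) * 2
        w = rng.normal(size=(L + 2, L + 2)) * 2
        scores = [s for s, _ in _enumerate_paths(e, w)]
        brute = np.logaddexp.reduce(scores)
        logZ, _ = crf_forward_np(e, w)
        assert logZ == pytest.approx(brute, abs=1e-8)

    @given(st.integers(1, 5), st.integers(2, 4), st.integers(0, 10_000))
    def test_viterbi_matches_enumeration(self, T, L, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=(T, L)) * 2
        w = rng.normal(size=(L + 2, L + 2)) * 2
        best_score = max(s for s, _ in _enumerate_paths(e, w))
        path, score = crf_viterbi(e, w)
        assert score == pytest.approx(best_score, abs=1e-8)
        assert score == pytest.approx(crf_path_score(e, path, w), abs=1e-10)

    def test_path_probabilities_sum_to_one(self, rng):
        e = rng.normal(size=(3, 3))
        w = rng.normal(size=(5, 5))
        logZ, _ = crf_forward_np(e, w)
        total = sum(np.exp(s - logZ) for s, _ in _enumerate_paths(e, w))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_loglik_nonpositive(self, rng):
        for _ in range(10):
            T, L = int(rng.integers(1, 5)), int(rng.integers(2, 4))
            e = rng.normal(size=(T, L))
            w = rng.normal(size=(L + 2, L + 2))
            tags = rng.integers(0, L, size=T)
            assert float(crf_log_likelihood(e, tags, w).data) <= 1e-12

    def test_tie_break_toward_lowest_tag_index(self):
        path, _ = crf_viterbi(np.zeros((4, 3)), np.zeros((5, 5)))
        assert path == [0, 0, 0, 0]

    def test_single_token_base_case(self, rng):
        e = rng.normal(size=(1, 4))
        w = rng.normal(size=(6, 6))
        path, score = crf_viterbi(e, w)
        totals = w[4, :4] + e[0] + w[:4, 5]
        assert path == [int(np.argmax(totals))]
        assert score == pytest.approx(float(totals.max()), abs=1e-12)

    def test_tag_outside_inventory_rejected(self):
        with pytest.raises(ConfigError):
            crf_log_likelihood(np.zeros((2, 3)), [0, 7], np.zeros((5, 5)))

    def test_gradient_matches_finite_differences(self, rng):
        e = rng.normal(size=(3, 3))
        w = rng.normal(size=(5, 5))
        tags = [0, 2, 1]
        et, wt = ad.parameter(e), ad.parameter(w)
        ad.backward(crf_log_likelihood(et, tags, wt))
        eps = 1e-6
        for idx in [(0, 0), (2, 2)]:
            e2, e3 = e.copy(), e.copy()
            e2[idx] += eps
            e3[idx] -= eps
            num = (float(crf_log_likelihood(e2, tags, w).data)
                   - float(crf_log_likelihood(e3, tags, w).data)) / (2 * eps)
            assert et.grad[idx] == pytest.approx(num, abs=1e-6)
        for idx in [(3, 0), (1, 4), (0, 1)]:
            w2, w3 = w.copy(), w.copy()
            w2[idx] += eps
            w3[idx] -= eps
            num = (float(crf_log_likelihood(e, tags, w2).data)
                   - float(crf_log_likelihood(e, tags, w3).data)) / (2 * eps)
            assert wt.grad[idx] == pytest.approx(num, abs=1e-6)


def _small_setup(tiny_pair, small_feature_configs, **cfg_kw):
    cfg, _, target, _ = tiny_pair
    defaults = dict(hidden_size=6, fc_size=8, learning_rate=0.02, batch_size=4,
                    epochs=2, dropout=0.3, early_stopping=False)
    defaults.update(cfg_kw)
    return target, LabelSet(cfg.target_labels), small_feature_configs[1], \
        TrainConfig(**defaults)


class TestTraining:
    def test_same_seed_same_data_bit_identical(self, tiny_pair,
                                               small_feature_configs):
        target, labels, fc, tc = _small_setup(tiny_pair, small_feature_configs)
        r1 = train_basic(target, labels, fc, tc, seed=3)
        r2 = train_basic(target, labels, fc, tc, seed=3)
        assert set(r1.params.blocks) == set(r2.params.blocks)
        for k in r1.params.blocks:
            assert np.array_equal(r1.params.blocks[k], r2.params.blocks[k]), k
        assert r1.history == r2.history

    def test_separable_corpus_reaches_perfect_training_f1(self):
        """50 unambiguous sentences: the tagger must fit them exactly
        within 30 epochs."""
        from trigrec.synthetic import SynthConfig, generate_domain_pair

        cfg = SynthConfig(n_target_docs=10, sentences_per_doc=5, seed=3,
                          ambiguity=0.0)
        _, target, _ = generate_domain_pair(cfg)
        fc = FeatureConfig(dim_word=16, dim_pos=4, dim_entity=6, dim_dep=8,
                           use_char=False)
        tc = TrainConfig(hidden_size=16, fc_size=24, learning_rate=0.02,
                         batch_size=4, epochs=30, dropout=0.2,
                         early_stopping=False)
        res = train_basic(target, LabelSet(cfg.target_labels), fc, tc, seed=1)
        assert res.evaluate(target).total_f1 == pytest.approx(100.0)

    def test_full_batch_descent_loss_non_increasing(self, tiny_pair,
                                                    small_feature_configs):
        target, labels, fc, tc = _small_setup(
            tiny_pair, small_feature_configs, optimizer="sgd",
            learning_rate=1e-3, batch_size=10_000, epochs=6, dropout=0.0,
            shuffle=False)
        res = train_basic(target, labels, fc, tc, seed=5)
        losses = [h["loss"] for h in res.history]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_inference_deterministic_dropout_off(self, tiny_pair,
                                                 small_feature_configs):
        target, labels, fc, tc = _small_setup(tiny_pair, small_feature_configs,
                                              epochs=1)
        res = train_basic(target, labels, fc, tc, seed=4)
        assert res.predict_tags(target) == res.predict_tags(target)

    def test_empty_corpus_rejected(self, small_feature_configs):
        from trigrec.corpus_io import Corpus

        with pytest.raises(ConfigError):
            TriggerModel(Corpus("t", []), LabelSet(("A",)),
                         small_feature_configs[1], TrainConfig())

    def test_summary_mentions_key_facts(self, tiny_pair, small_feature_configs):
        target, labels, fc, tc = _small_setup(tiny_pair, small_feature_configs,
                                              epochs=1)
        res = train_basic(target, labels, fc, tc, seed=0)
        text = res.summary()
        assert "trigger types" in text and "seed" in text


class TestCheckpoint:
    def test_save_load_roundtrip_and_partial(self, tiny_pair,
                                             small_feature_configs, tmp_path,
                                             rng):
        from trigrec.features import build_vocab

        _, source, _, _ = tiny_pair
        fc = small_feature_configs[0]
        bundle = network.init_parameters(build_vocab(source), fc,
                                         ("O", "A", "B"), 4, 6, rng)
        bundle.save(tmp_path / "ckpt")
        full = ParameterBundle.load(tmp_path / "ckpt")
        assert full.allclose(bundle)
        partial = ParameterBundle.load(tmp_path / "ckpt",
                                       blocks=["fc.W", "crf.trans"])
        assert set(partial.blocks) == {"fc.W", "crf.trans"}
        from trigrec.errors import PlanError

        with pytest.raises(PlanError):
            ParameterBundle.load(tmp_path / "ckpt", blocks=["nope"])
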