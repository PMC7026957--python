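"""The NumPy LSTM generator: architecture, gradients, training, sampling."""

import copy

import numpy as np
import pytest

from molcycle.corpus import TokenVocabulary, build_vocabulary, encode
from molcycle.generator import (
    GeneratorConfig,
    GeneratorModel,
    build_model,
    lstm_parameter_count,
)

FULL_SCALE = dict(vocab_size=53, n_layers=3, hidden_size=1024)


def _tiny_model(n_layers=2, hidden=5, seed=3, **kw):
    vocab = TokenVocabulary(sorted(set("G\nCO()")))
    cfg = GeneratorConfig(vocab_size=vocab.size, n_layers=n_layers,
                          hidden_size=hidden, dropout=0.0, window_length=8,
                          batch_size=4, seed=seed, **kw)
    return GeneratorModel(cfg, vocab)


class TestArchitecture:
    def test_full_scale_parameter_count_single_bias(self):
        # closed-form gate sum: 4*(1024*(53+1024)+1024) + 2*4*(1024*2048+1024)
        #                       + (1024*53+53)
        assert lstm_parameter_count(**FULL_SCALE, biases_per_gate=1) == 21_255_221

    def test_full_scale_parameter_count_dual_bias(self):
        assert lstm_parameter_count(**FULL_SCALE, biases_per_gate=2) == 21_267_509

    def test_both_conventions_round_to_21_million(self):
        for b in (1, 2):
            n = lstm_parameter_count(**FULL_SCALE, biases_per_gate=b)
            assert round(n / 1e6) == 21

    def test_minimal_gate_expansion_by_hand(self):
        # one layer, one unit, one-symbol vocabulary:
        # 4*(1*(1+1)+1) + (1*1+1) = 14
        assert lstm_parameter_count(1, 1, 1, biases_per_gate=1) == 14

    def test_model_report_matches_closed_form(self):
        m = _tiny_model(n_layers=2, hidden=7)
        assert m.parameter_count() == lstm_parameter_count(m.vocab.size, 2, 7)

    def test_doubling_hidden_size_strictly_increases_count(self):
        assert (lstm_parameter_count(20, 2, 64)
                < lstm_parameter_count(20, 2, 128))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(vocab_size=0)
        with pytest.raises(ValueError):
            GeneratorConfig(vocab_size=5, dropout=1.0)

    def test_vocab_size_mismatch_rejected(self):
        vocab = TokenVocabulary(sorted(set("G\nC")))
        with pytest.raises(ValueError):
            build_model(GeneratorConfig(vocab_size=99), vocab)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        """Analytic BPTT gradients agree with central finite differences."""
        m = _tiny_model()
        for k in m.params:
            m.params[k] = m.params[k].astype(np.float64)
        rng = np.random.default_rng(0)
        X = rng.integers(0, m.vocab.size, (2, 6))
        Y = rng.integers(0, m.vocab.size, (2, 6))
        _, grads = m._loss_and_grads(X, Y, train_rng=None)
        eps = 1e-6
        rng2 = np.random.default_rng(1)
        for k, p in m.params.items():
            flat = p.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = m._loss_and_grads(X, Y, None)
                flat[idx] = orig - eps
                lm, _ = m._loss_and_grads(X, Y, None)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[k].reshape(-1)[idx]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), k

    def test_softmax_is_a_distribution(self):
        m = _tiny_model()
        logits, _ = m._forward(np.zeros((3, 4), dtype=np.int64))
        p = m._softmax(logits)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, rtol=1e-5)


class TestTraining:
    def test_untrained_cross_entropy_is_near_uniform(self, small_encoded,
                                                     small_vocab):
        cfg = GeneratorConfig.desk(small_vocab.size, window_length=40, seed=5)
        m = GeneratorModel(cfg, small_vocab)
        X, Y = small_encoded.windows()
        ce = m.cross_entropy(X[:16], Y[:16])
        assert abs(ce - np.log(small_vocab.size)) < 0.2

    def test_training_beats_uniform_on_holdout(self, trained_small_model,
                                               small_encoded, small_vocab):
        X, Y = small_encoded.windows()
        n_hold = max(1, X.shape[0] // 20)
        ce = trained_small_model.cross_entropy(X[-n_hold:], Y[-n_hold:])
        assert ce < np.log(small_vocab.size)
        trace = trained_small_model.loss_trace
        assert trace[-1]["holdout_loss"] < trace[0]["holdout_loss"]

    def test_vocabulary_mismatch_raises(self, small_encoded):
        other = TokenVocabulary(sorted(set("G\nXY")))
        m = GeneratorModel(GeneratorConfig.desk(other.size), other)
        with pytest.raises(ValueError):
            m.train(small_encoded)

    def test_fine_tuning_raises_likelihood_of_selected_molecules(
        self, trained_small_model
    ):
        model = copy.deepcopy(trained_small_model)
        target = ["Cc1ccccc1O", "CCC(=O)O", "OC1CCNC1", "Cc1ccncc1"]
        before = model.mean_log_likelihood(target)
        model.fine_tune(target, seed=2)
        model.fine_tune(target, seed=3)
        after = model.mean_log_likelihood(target)
        assert after > before

    def test_fine_tune_skips_out_of_vocabulary_molecules(self, trained_small_model):
        model = copy.deepcopy(trained_small_model)
        model.fine_tune(["CCO" * 20, "C%47"], seed=0)  # '%47' chars unseen
        with pytest.raises(ValueError):
            model.fine_tune(["ZZZZ"], seed=0)

    def test_empty_selection_rejected(self, trained_small_model):
        with pytest.raises(ValueError):
            copy.deepcopy(trained_small_model).fine_tune([])


class TestSampling:
    def test_molecules_are_delimiter_free_and_deterministic(
        self, trained_small_model
    ):
        mols1, d1 = trained_small_model.sample_molecules(2000, seed=4)
        mols2, d2 = trained_small_model.sample_molecules(2000, seed=4)
        assert mols1 == mols2 and d1 == d2
        assert sum(len(m) for m in mols1) + len(mols1) + d1 >= 2000
        for m in mols1:
            assert "G" not in m and "\n" not in m

    def test_different_seeds_differ(self, trained_small_model):
        a, _ = trained_small_model.sample_molecules(1500, seed=1)
        b, _ = trained_small_model.sample_molecules(1500, seed=2)
        assert a != b

    def test_delta_distribution_ignores_seed(self):
        """With logits forced to a point mass on the end symbol, sampling is
        deterministic no matter the seed."""
        m = _tiny_model()
        m.params["Wy"][:] = 0.0
        m.params["by"][:] = -50.0
        m.params["by"][m.vocab.end_index] = 50.0
        a, _ = m.sample_molecules(50, seed=0)
        b, _ = m.sample_molecules(50, seed=12345)
        assert a == b == [""] * len(a)

    def test_runaway_chains_are_discarded(self):
        m = _tiny_model(max_sample_length=10)
        # point mass on a regular character: no chain ever terminates
        c_idx = m.vocab.index_of["C"]
        m.params["Wy"][:] = 0.0
        m.params["by"][:] = -50.0
        m.params["by"][c_idx] = 50.0
        mols, discarded = m.sample_molecules(100, seed=0, n_chains=4)
        assert mols == []
        assert discarded > 0

    def test_character_stream_contract(self, trained_small_model):
        stream = trained_small_model.sample_characters(500, seed=6)
        assert len(stream) >= 500
        candidates = stream.split("\n")
        assert all("G" not in c for c in candidates)


class TestPersistence:
    def test_checkpoint_round_trip(self, trained_small_model, tmp_path):
        path = tmp_path / "model.npz"
        trained_small_model.save(path)
        restored = GeneratorModel.load(path)
        assert restored.vocab.symbols == trained_small_model.vocab.symbols
        for k, v in trained_small_model.params.items():
            np.testing.assert_array_equal(restored.params[k], v)
        a, _ = trained_small_model.sample_molecules(300, seed=9)
        b, _ = restored.sample_molecules(300, seed=9)
        assert a == b
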