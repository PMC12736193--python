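"""Affinity regressor: architecture, metrics oracle, training behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agentmol.data_io import split_dataset
from agentmol.dti_rcnn import (
    RcnnConfig,
    build_rcnn,
    encode_dataset,
    evaluate_regression,
    predict_pki,
    repeat_experiment,
    train_rcnn,
)
from agentmol.fixtures import FixtureSpec, make_paired_corpus
from agentmol.tokenization import build_char_vocab


def _brute_force_metrics(y, p):
    """Independent recomputation of R, R^2, RMSE from their definitions."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    ybar, pbar = y.mean(), p.mean()
    r = ((y - ybar) * (p - pbar)).sum() / np.sqrt(
        ((y - ybar) ** 2).sum() * ((p - pbar) ** 2).sum()
    )
    r2 = 1.0 - ((y - p) ** 2).sum() / ((y - ybar) ** 2).sum()
    rmse = np.sqrt(((y - p) ** 2).mean())
    return r, r2, rmse


class TestArchitecture:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            RcnnConfig(filters=(32, 32))  # wrong number of conv layers
        with pytest.raises(ValueError):
            RcnnConfig(filters=(32, 32, 32, 64, 64, 128))  # filter out of range

    def test_pooling_arithmetic(self):
        model = build_rcnn(RcnnConfig(), vocab_size=30)
        assert model.conv_lengths == [800, 400, 200, 100, 50, 25, 12]
        assert model.flat_len == 12 * 64

    def test_scalar_output_and_finite_on_all_pad(self):
        model = build_rcnn(RcnnConfig(), vocab_size=30)
        pred = predict_pki(model, np.zeros(800, dtype=int))
        assert isinstance(pred, float) and np.isfinite(pred)

    def test_wrong_length_rejected(self):
        model = build_rcnn(RcnnConfig(), vocab_size=30)
        with pytest.raises(ValueError):
            predict_pki(model, np.zeros(700, dtype=int))

    def test_prediction_invariant_to_batch_composition(self, small_rcnn):
        model, vocab, _ = small_rcnn
        rng = np.random.default_rng(0)
        x = rng.integers(0, vocab.size, size=800)
        other = rng.integers(0, vocab.size, size=(4, 800))
        alone = predict_pki(model, x)
        batched = predict_pki(model, np.vstack([other, x[None, :]]))
        assert alone == pytest.approx(float(batched[-1]), abs=1e-9)
        same = predict_pki(model, np.vstack([x, x]))
        assert float(same[0]) == pytest.approx(float(same[1]), abs=1e-12)


class TestEvaluateRegression:
    def test_identity_case(self):
        m = evaluate_regression([1, 2, 3], [1, 2, 3])
        assert m.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_prediction_r2_zero(self):
        m = evaluate_regression([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.r_squared == pytest.approx(0.0)

    def test_hand_case(self):
        m = evaluate_regression([0, 1, 2, 3], [0.5, 1.5, 2.5, 3.5])
        assert m.rmse == pytest.approx(0.5)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.r_squared == pytest.approx(0.8)

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 50))
            y = rng.normal(5, 2, size=n)
            p = y + rng.normal(0, 1, size=n)
            m = evaluate_regression(y, p)
            r, r2, rmse = _brute_force_metrics(y, p)
            assert m.pearson_r == pytest.approx(r, abs=1e-9)
            assert m.r_squared == pytest.approx(r2, abs=1e-9)
            assert m.rmse == pytest.approx(rmse, abs=1e-9)

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            evaluate_regression([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            evaluate_regression([2, 2, 2], [1, 2, 3])

    @given(st.integers(min_value=0, max_value=1000))
    def test_rmse_matches_direct_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=10)
        p = rng.normal(size=10)
        m = evaluate_regression(y, p)
        assert m.rmse == pytest.approx(float(np.sqrt(np.mean((y - p) ** 2))), abs=1e-9)


class TestTraining:
    def test_learning_happens(self, small_rcnn):
        _, _, history = small_rcnn
        assert history[-1]["val_loss"] < history[0]["val_loss"]

    def test_seeded_training_reproducible(self, fixture_corpus):
        vocab = build_char_vocab(fixture_corpus)
        tr, va = split_dataset(fixture_corpus, 0.7, seed=1)
        enc_t, enc_v = encode_dataset(tr, vocab), encode_dataset(va, vocab)
        cfg = RcnnConfig(epochs=1, batch_size=32, seed=9)
        _, h1 = train_rcnn(build_rcnn(cfg, vocab.size), enc_t, enc_v)
        _, h2 = train_rcnn(build_rcnn(cfg, vocab.size), enc_t, enc_v)
        assert h1[0]["train_loss"] == pytest.approx(h2[0]["train_loss"], rel=1e-9)
        assert h1[0]["val_r"] == pytest.approx(h2[0]["val_r"], rel=1e-9)

    def test_memorizes_tiny_training_set(self):
        # draw whose targets span ~2-5 so the overfit check is non-degenerate
        ds = make_paired_corpus(FixtureSpec(n_pairs=5, noise_sd=0.0, seed=22))
        vocab = build_char_vocab(ds)
        X, y = encode_dataset(ds, vocab)
        cfg = RcnnConfig(epochs=300, batch_size=5, seed=2)
        model = build_rcnn(cfg, vocab.size)
        model, _ = train_rcnn(model, (X, y), (X, y))
        preds = predict_pki(model, X)
        assert np.max(np.abs(preds - y)) < 0.2

    def test_noise_degrades_fit(self):
        """Same training budget, noisier targets -> worse validation RMSE."""
        rmse = {}
        for noise in (0.0, 1.5):
            ds = make_paired_corpus(FixtureSpec(n_pairs=200, noise_sd=noise, seed=13))
            vocab = build_char_vocab(ds)
            tr, va = split_dataset(ds, 0.7, seed=1)
            cfg = RcnnConfig(epochs=5, batch_size=16, loss="mae", seed=1)
            model = build_rcnn(cfg, vocab.size)
            _, hist = train_rcnn(model, encode_dataset(tr, vocab), encode_dataset(va, vocab))
            rmse[noise] = hist[-1]["val_rmse"]
        assert rmse[1.5] > rmse[0.0]


class TestRepeatExperiment:
    def test_bookkeeping_two_repeats(self):
        ds = make_paired_corpus(FixtureSpec(n_pairs=60, noise_sd=0.0, seed=17))
        cfg = RcnnConfig(epochs=2, batch_size=16)
        summary = repeat_experiment(ds, cfg, n_repeats=2, seeds=[1, 2])
        assert summary.n_repeats == 2
        for key in ("val_r", "val_r2_final", "val_rmse_final", "val_r2_epoch1",
                    "train_r", "train_loss_final"):
            mean, sd = summary.metrics[key]
            assert np.isfinite(mean) and sd >= 0

    def test_identical_seeds_zero_sd(self):
        ds = make_paired_corpus(FixtureSpec(n_pairs=40, noise_sd=0.0, seed=19))
        cfg = RcnnConfig(epochs=1, batch_size=16)
        summary = repeat_experiment(ds, cfg, n_repeats=2, seeds=[3, 3])
        for mean, sd in summary.metrics.values():
            assert sd == pytest.approx(0.0, abs=1e-9)

    def test_seed_count_mismatch(self):
        ds = make_paired_corpus(FixtureSpec(n_pairs=40, seed=19))
        with pytest.raises(ValueError):
            repeat_experiment(ds, RcnnConfig(epochs=1), n_repeats=3, seeds=[1, 2])
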