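"""Balanced batching, gradient partition, determinism and prediction."""

import numpy as np
import pytest

from cxrda.architectures import EncoderConfig, build_bundle
from cxrda.objectives import LossWeights
from cxrda.training import (
    BalancedBatchIterator,
    BatchPair,
    TrainingConfig,
    TrainingError,
    Trainer,
    balanced_batch_iterator,
    fit,
    load_bundle,
    predict,
    predict_labels,
    save_bundle,
)

ENC16 = EncoderConfig(head_filters=16, input_side=16)


def _snapshot(component):
    return [{k: p.copy() for k, p in l.params.items()} for l in component.iter_layers()]


def _unchanged(component, snap):
    return all(np.array_equal(l.params[k], s[k])
               for l, s in zip(component.iter_layers(), snap) for k in s)


def _batch(rng, bs=4, side=16):
    xs = rng.random((bs, side, side, 3), dtype=np.float32)
    ys = np.zeros((bs, 2), dtype=np.float32)
    ys[: bs // 2, 0] = 1.0
    ys[bs // 2 :, 1] = 1.0
    return BatchPair(xs, ys, np.ones(bs), rng.random((bs, side, side, 3), dtype=np.float32))


class TestBatchIterator:
    def test_exact_division(self):
        it = BalancedBatchIterator(32, 20, 16, np.random.default_rng(0))
        batches = list(it.epoch())
        assert len(batches) == 2
        assert sorted(np.concatenate([b[0] for b in batches])) == list(range(32))

    def test_wraparound_coverage_and_target_cycling(self):
        it = BalancedBatchIterator(100, 30, 16, np.random.default_rng(1))
        batches = list(it.epoch())
        assert len(batches) == 7
        src = np.concatenate([b[0] for b in batches])
        assert len(src) == 7 * 16
        assert set(src) == set(range(100))  # every source sample used >= once
        tgt = np.concatenate([b[1] for b in batches])
        assert len(tgt) == 7 * 16
        # the cycled pool traverses all 30 targets before reshuffling
        assert set(tgt[:30]) == set(range(30))
        assert set(tgt[30:60]) == set(range(30))

    def test_same_seed_identical_sequences(self):
        def collect(seed):
            it = BalancedBatchIterator(23, 11, 8, np.random.default_rng(seed))
            return [(s.tolist(), t.tolist()) for _ in range(3) for s, t in it.epoch()]

        assert collect(5) == collect(5)
        assert collect(5) != collect(6)

    def test_empty_set_rejected(self):
        with pytest.raises(TrainingError):
            BalancedBatchIterator(0, 5, 4, np.random.default_rng(0))

    def test_batch_pairs_have_equal_halves(self, rng):
        xs = rng.random((10, 8, 8, 3), dtype=np.float32)
        ys = np.zeros((10, 2), dtype=np.float32)
        ys[:4, 1] = 1.0
        ys[4:, 0] = 1.0
        xt = rng.random((6, 8, 8, 3), dtype=np.float32)
        for pair in balanced_batch_iterator((xs, ys), xt, 4, seed=0):
            assert len(pair.source_images) == len(pair.target_images) == 4
            assert len(pair.source_labels) == len(pair.source_weights) == 4


class TestGradientPartition:
    def test_discriminator_phase_touches_only_discriminator(self, rng):
        bundle = build_bundle("rdrda", ENC16, seed=0)
        trainer = Trainer(bundle, TrainingConfig.desk("rdrda"))
        snaps = {n: _snapshot(c) for n, c in bundle.components().items()}
        trainer.discriminator_phase(_batch(rng))
        assert not _unchanged(bundle.discriminator, snaps["discriminator"])
        for name in ("encoder", "classifier", "decoder"):
            assert _unchanged(bundle.components()[name], snaps[name]), name

    def test_encoder_phase_leaves_discriminator_untouched(self, rng):
        bundle = build_bundle("rdrda", ENC16, seed=0)
        trainer = Trainer(bundle, TrainingConfig.desk("rdrda"))
        batch = _batch(rng)
        trainer.discriminator_phase(batch)
        snap_d = _snapshot(bundle.discriminator)
        snaps = {n: _snapshot(c) for n, c in bundle.components().items()}
        trainer.encoder_phase(batch)
        assert _unchanged(bundle.discriminator, snap_d)
        for name in ("encoder", "classifier", "decoder"):
            assert not _unchanged(bundle.components()[name], snaps[name]), name

    def test_source_only_step_has_no_decoder_or_discriminator(self, rng):
        bundle = build_bundle("source_only", ENC16, seed=0)
        assert bundle.decoder is None and bundle.discriminator is None
        trainer = Trainer(bundle, TrainingConfig.desk("source_only"))
        losses = trainer.train_step(_batch(rng))
        assert set(losses) == {"classification"}

    def test_drda_updates_decoder_directly_even_with_lambda_r_zero(self, rng):
        cfg = TrainingConfig(mode="drda", learning_rate=1e-3, epochs=1, batch_size=4,
                             loss_weights=LossWeights(1.0, 0.0, 0.0))
        bundle = build_bundle("drda", ENC16, seed=0)
        trainer = Trainer(bundle, cfg)
        snap_dt = _snapshot(bundle.decoder)
        losses = trainer.train_step(_batch(rng))
        assert "reconstruction" in losses
        assert not _unchanged(bundle.decoder, snap_dt)

    def test_mode_bundle_mismatch_rejected(self):
        bundle = build_bundle("drda", ENC16, seed=0)
        with pytest.raises(TrainingError):
            Trainer(bundle, TrainingConfig.desk("rdrda"))
        with pytest.raises(TrainingError):
            Trainer(bundle, TrainingConfig.desk("source_only"))


class TestFit:
    def test_history_lengths_and_keys(self, tiny_classification_data):
        xs, ys, xt = tiny_classification_data
        cfg = TrainingConfig(mode="drda", learning_rate=1e-3, epochs=2, batch_size=8, seed=0)
        history = fit(build_bundle("drda", ENC16, seed=0), (xs, ys), xt, cfg)
        assert set(history) == {"classification", "reconstruction"}
        assert all(len(v) == 2 for v in history.values())

    def test_same_seed_reproduces_final_losses(self, tiny_classification_data):
        xs, ys, xt = tiny_classification_data
        cfg = TrainingConfig(mode="rdrda", learning_rate=1e-3, epochs=2, batch_size=8, seed=3)
        h1 = fit(build_bundle("rdrda", ENC16, seed=3), (xs, ys), xt, cfg)
        h2 = fit(build_bundle("rdrda", ENC16, seed=3), (xs, ys), xt, cfg)
        assert h1 == h2

    def test_rdrda_with_zero_adversarial_weight_matches_drda(self, tiny_classification_data):
        """With lambda_d = 0 the regularized scheme reproduces the plain
        reconstruction scheme's loss trajectories under shared seeds."""
        xs, ys, xt = tiny_classification_data
        h_drda = fit(build_bundle("drda", ENC16, seed=7), (xs, ys), xt,
                     TrainingConfig(mode="drda", learning_rate=1e-3, epochs=3,
                                    batch_size=8, seed=7))
        h_rdrda = fit(build_bundle("rdrda", ENC16, seed=7), (xs, ys), xt,
                      TrainingConfig(mode="rdrda", learning_rate=1e-3, epochs=3,
                                     batch_size=8, seed=7,
                                     loss_weights=LossWeights(0.5, 0.5, 0.0)))
        np.testing.assert_allclose(h_rdrda["classification"], h_drda["classification"],
                                   rtol=1e-10)
        np.testing.assert_allclose(h_rdrda["reconstruction"], h_drda["reconstruction"],
                                   rtol=1e-10)

    def test_non_finite_loss_aborts_with_loss_name(self, tiny_classification_data):
        xs, ys, xt = tiny_classification_data
        bad = xt.copy()
        bad[0, 0, 0, 0] = np.nan
        cfg = TrainingConfig(mode="drda", learning_rate=1e-3, epochs=1, batch_size=8)
        with pytest.raises(TrainingError, match="reconstruction"):
            fit(build_bundle("drda", ENC16, seed=0), (xs, ys), bad, cfg)

    def test_missing_target_set_rejected(self, tiny_classification_data):
        xs, ys, _ = tiny_classification_data
        cfg = TrainingConfig(mode="drda", learning_rate=1e-3, epochs=1, batch_size=8)
        with pytest.raises(TrainingError, match="target"):
            fit(build_bundle("drda", ENC16, seed=0), (xs, ys), None, cfg)


class TestFrozenBackbone:
    def test_backbone_parameters_fixed_during_training(self, tiny_classification_data):
        xs, ys, _ = tiny_classification_data
        enc_cfg = EncoderConfig(head_filters=16, input_side=16, backbone_frozen=True)
        bundle = build_bundle("source_only", enc_cfg, seed=0)
        frozen = [l for l in bundle.encoder.iter_layers() if not l.trainable and l.params]
        assert frozen
        before = [{k: p.copy() for k, p in l.params.items()} for l in frozen]
        fit(bundle, (xs, ys), None,
            TrainingConfig(mode="source_only", learning_rate=1e-2, epochs=1, batch_size=8))
        for l, snap in zip(frozen, before):
            for k in snap:
                assert np.array_equal(l.params[k], snap[k])


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    xs = rng.random((16, 16, 16, 3), dtype=np.float32)
    ys = np.zeros((16, 2), dtype=np.float32)
    ys[:6, 1] = 1.0
    ys[6:, 0] = 1.0
    bundle = build_bundle("source_only", ENC16, seed=1)
    fit(bundle, (xs, ys), None,
        TrainingConfig(mode="source_only", learning_rate=1e-3, epochs=1, batch_size=8))
    return bundle, rng.random((7, 16, 16, 3), dtype=np.float32)


class TestPredict:

    def test_probabilities_sum_to_one(self, trained):
        bundle, x = trained
        probs = predict(bundle, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_and_batch_equals_loop(self, trained):
        bundle, x = trained
        p1 = predict(bundle, x)
        p2 = predict(bundle, x)
        per_sample = np.concatenate([predict(bundle, x[i : i + 1]) for i in range(len(x))])
        assert np.array_equal(p1, p2)
        np.testing.assert_allclose(p1, per_sample, atol=1e-6)

    def test_labels_tie_goes_to_normal(self, trained):
        bundle, x = trained
        labels = predict_labels(bundle, x)
        probs = predict(bundle, x)
        for label, p in zip(labels, probs):
            assert label == ("cardiomegaly" if p[1] > 0.5 else "normal")

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        bundle, x = trained
        save_bundle(bundle, tmp_path / "ck.npz")
        clone = build_bundle("source_only", ENC16, seed=99)
        load_bundle(clone, tmp_path / "ck.npz")
        np.testing.assert_array_equal(predict(bundle, x), predict(clone, x))
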