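"""Training regimes: source-only, reconstruction adaptation (DRDA) and its
adversarially regularized variant (RDRDA).

The update partition is explicit: the discriminator's parameters are updated
only by the domain-discrimination loss, the classifier's only by the
(weighted) classification loss, the decoder's only by the reconstruction
loss, and the encoder's by the convex combination of classification,
reconstruction and (RDRDA only) inverted-label adversarial losses.  Within a
step the discriminator is updated first, on the current encoder's features;
the encoder/classifier/decoder group follows.  One Adam optimizer per
component keeps the partition auditable.

Cross-domain batches are balanced: every batch holds ``bs`` labeled source
samples and ``bs`` unlabeled target samples.  The source set is traversed in
a seeded shuffle without replacement, the final short batch wrapping around
so that every source sample is used at least once per epoch; the target set
is cycled from an independently shuffled list, reshuffled at each wrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn, objectives
from .architectures import ModelBundle
from .nn import Adam
from .objectives import LossWeights

MODES = ("source_only", "drda", "rdrda")


class TrainingError(ValueError):
    pass


def default_loss_weights(mode: str) -> LossWeights:
    if mode == "source_only":
        return LossWeights(1.0, 0.0, 0.0)
    if mode == "drda":
        return LossWeights.drda()
    if mode == "rdrda":
        return LossWeights.rdrda()
    raise TrainingError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol.

    The reference protocol is Adam at a fixed learning rate of 1e-6 for 200
    epochs with batch size 16.  ``desk()`` returns the desk-scale profile
    (1e-3, 30 epochs) used for small scratch-backbone runs.
    """

    mode: str = "source_only"
    learning_rate: float = 1e-6
    epochs: int = 200
    batch_size: int = 16
    loss_weights: LossWeights | None = None
    seed: int = 0
    checkpoint_path: str | None = None

    def validate(self) -> None:
        if self.mode not in MODES:
            raise TrainingError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.batch_size < 2:
            raise TrainingError("batch_size must be >= 2")
        if self.epochs < 1:
            raise TrainingError("epochs must be >= 1")
        lw = self.resolved_loss_weights()
        lw.validate()
        if self.mode == "source_only" and (lw.lambda_r or lw.lambda_d):
            raise TrainingError("source_only uses the classification loss alone")
        if self.mode == "drda" and lw.lambda_d:
            raise TrainingError("drda requires lambda_d = 0 (no discriminator)")

    def resolved_loss_weights(self) -> LossWeights:
        return self.loss_weights if self.loss_weights is not None else default_loss_weights(self.mode)

    @classmethod
    def desk(cls, mode: str, seed: int = 0, **kw) -> "TrainingConfig":
        return cls(mode=mode, learning_rate=1e-3, epochs=30, batch_size=16, seed=seed, **kw)


@dataclass
class BatchPair:
    """bs labeled source samples plus bs unlabeled target samples."""

    source_images: np.ndarray
    source_labels: np.ndarray  # one-hot (bs, 2)
    source_weights: np.ndarray
    target_images: np.ndarray | None


class BalancedBatchIterator:
    """Index-level balanced batching with persistent target cycling."""

    def __init__(self, n_source: int, n_target: int | None, batch_size: int,
                 rng: np.random.Generator):
        if n_source < 1 or (n_target is not None and n_target < 1):
            raise TrainingError("source and target sets must be nonempty")
        self.n_source, self.n_target, self.bs = n_source, n_target, batch_size
        self.rng = rng
        self._target_pool: list[int] = []

    @property
    def batches_per_epoch(self) -> int:
        return -(-self.n_source // self.bs)

    def _next_target(self, count: int) -> np.ndarray:
        out = []
        while len(out) < count:
            if not self._target_pool:
                self._target_pool = list(self.rng.permutation(self.n_target))
            out.append(self._target_pool.pop())
        return np.asarray(out)

    def epoch(self):
        """Yield (source_idx, target_idx) pairs; target_idx is None when the
        iterator was built without a target set."""
        perm = self.rng.permutation(self.n_source)
        for b in range(self.batches_per_epoch):
            idx = np.arange(b * self.bs, (b + 1) * self.bs) % self.n_source
            src = perm[idx]
            tgt = self._next_target(self.bs) if self.n_target is not None else None
            yield src, tgt


def balanced_batch_iterator(source_train: tuple[np.ndarray, np.ndarray],
                            target_train: np.ndarray | None,
                            batch_size: int, seed: int):
    """One epoch of ``BatchPair``s over in-memory arrays.

    ``source_train`` is (images, one-hot labels); ``target_train`` is an
    unlabeled image array or None.  Sample weights are computed on the full
    source training set.
    """
    xs, ys = source_train
    w = objectives.sample_weights(ys)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA7C4]))
    it = BalancedBatchIterator(len(xs), None if target_train is None else len(target_train),
                               batch_size, rng)
    for src, tgt in it.epoch():
        yield BatchPair(xs[src], ys[src], w[src],
                        None if tgt is None else target_train[tgt])


class Trainer:
    """Stateful trainer binding a ModelBundle to a TrainingConfig."""

    def __init__(self, bundle: ModelBundle, cfg: TrainingConfig):
        cfg.validate()
        if cfg.mode in ("drda", "rdrda") and bundle.decoder is None:
            raise TrainingError(f"mode {cfg.mode!r} needs a decoder in the bundle")
        if cfg.mode == "rdrda" and bundle.discriminator is None:
            raise TrainingError("mode 'rdrda' needs a discriminator in the bundle")
        if cfg.mode == "source_only" and (bundle.decoder or bundle.discriminator):
            raise TrainingError("source_only bundle must not carry decoder/discriminator")
        self.bundle, self.cfg = bundle, cfg
        self.weights = cfg.resolved_loss_weights()
        lr = cfg.learning_rate
        self.opt = {name: Adam(comp, lr) for name, comp in bundle.components().items()}

    def discriminator_phase(self, batch: BatchPair) -> dict[str, float]:
        """Update the discriminator alone on current encoder features
        (source labeled 1, target 0).  Batch-norm running statistics are
        frozen here so they accumulate once per step, in the encoder phase."""
        bundle = self.bundle
        bs = len(batch.source_images)
        E, D = bundle.encoder, bundle.discriminator
        bundle.set_training(True)
        E.freeze_bn_stats(True)
        f_s = E.forward(batch.source_images)
        f_t = E.forward(batch.target_images)
        E.freeze_bn_stats(False)
        D.zero_grads()
        d_s = D.forward(f_s)
        gs, _ = objectives.discriminator_loss_grads(d_s, np.zeros(1), bs)
        D.backward(gs.astype(d_s.dtype))
        d_t = D.forward(f_t)
        _, gt = objectives.discriminator_loss_grads(np.ones(1), d_t, bs)
        D.backward(gt.astype(d_t.dtype))
        loss = objectives.discriminator_loss(d_s, d_t, bs)
        self.opt["discriminator"].step()
        D.zero_grads()
        return {"discriminator": loss}

    def encoder_phase(self, batch: BatchPair) -> dict[str, float]:
        """Update the encoder/classifier/decoder group: classifier by the
        weighted classification loss, decoder by the reconstruction loss,
        encoder by their convex combination (+ adversarial term in rdrda)."""
        cfg, lw = self.cfg, self.weights
        bundle = self.bundle
        bs = len(batch.source_images)
        E, CS = bundle.encoder, bundle.classifier
        DT, D = bundle.decoder, bundle.discriminator
        bundle.set_training(True)
        losses: dict[str, float] = {}
        E.zero_grads()
        CS.zero_grads()
        if DT is not None:
            DT.zero_grads()

        f_s = E.forward(batch.source_images)
        probs = CS.forward(f_s)
        lc = objectives.classification_loss(probs, batch.source_labels,
                                            batch.source_weights, bs)
        losses["classification"] = lc
        g_probs = objectives.classification_loss_grad(
            probs, batch.source_labels, batch.source_weights, bs)
        g_fs = CS.backward(g_probs.astype(f_s.dtype))
        lam_c = 1.0 if cfg.mode == "source_only" else lw.lambda_c
        E.backward(lam_c * g_fs)

        if cfg.mode in ("drda", "rdrda"):
            f_t = E.forward(batch.target_images)
            recon = DT.forward(f_t)
            lr_loss = objectives.reconstruction_loss(batch.target_images, recon, bs)
            losses["reconstruction"] = lr_loss
            g_recon = objectives.reconstruction_loss_grad(
                batch.target_images, recon, bs).astype(recon.dtype)
            g_ft = lw.lambda_r * DT.backward(g_recon)
            if cfg.mode == "rdrda":
                d_t = D.forward(f_t)
                losses["adversarial"] = objectives.adversarial_loss(d_t, bs)
                g_dt = objectives.adversarial_loss_grad(d_t, bs).astype(d_t.dtype)
                g_ft = g_ft + lw.lambda_d * D.backward(g_dt)
                D.zero_grads()  # theta_D is never updated by the adversarial loss
            E.backward(g_ft.astype(f_t.dtype))

        self.opt["encoder"].step()
        self.opt["classifier"].step()
        if DT is not None:
            self.opt["decoder"].step()
        return losses

    def train_step(self, batch: BatchPair) -> dict[str, float]:
        """One optimization step: discriminator phase first (rdrda only),
        then the encoder/classifier/decoder group. Returns per-loss scalars."""
        losses: dict[str, float] = {}
        if self.cfg.mode == "rdrda":
            losses.update(self.discriminator_phase(batch))
        losses.update(self.encoder_phase(batch))
        for name, value in losses.items():
            if not np.isfinite(value):
                raise TrainingError(f"non-finite {name} loss ({value}) during training")
        return losses


def fit(bundle: ModelBundle,
        source_train: tuple[np.ndarray, np.ndarray],
        target_train: np.ndarray | None,
        cfg: TrainingConfig) -> dict[str, list[float]]:
    """Train for ``cfg.epochs`` epochs; returns per-epoch mean loss history.

    ``source_train`` is (images NHWC in [0,1], one-hot labels); the target
    set is an unlabeled image array (required for drda/rdrda).  Fully seeded:
    data order, dropout and initialization all derive from fixed streams.
    """
    cfg.validate()
    xs, ys = source_train
    if len(xs) == 0:
        raise TrainingError("empty source training set")
    if cfg.mode in ("drda", "rdrda"):
        if target_train is None or len(target_train) == 0:
            raise TrainingError(f"mode {cfg.mode!r} needs unlabeled target images")
    trainer = Trainer(bundle, cfg)
    w = objectives.sample_weights(ys)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBA7C4]))
    n_target = None if cfg.mode == "source_only" else len(target_train)
    iterator = BalancedBatchIterator(len(xs), n_target, cfg.batch_size, rng)
    history: dict[str, list[float]] = {}
    for _epoch in range(cfg.epochs):
        sums: dict[str, float] = {}
        count = 0
        for src, tgt in iterator.epoch():
            batch = BatchPair(xs[src], ys[src], w[src],
                              None if tgt is None else target_train[tgt])
            losses = trainer.train_step(batch)
            for k, v in losses.items():
                sums[k] = sums.get(k, 0.0) + v
            count += 1
        for k, v in sums.items():
            history.setdefault(k, []).append(v / count)
    bundle.set_training(False)
    if cfg.checkpoint_path:
        save_bundle(bundle, cfg.checkpoint_path)
    return history


def predict(bundle: ModelBundle, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class probabilities CS(E(x)) in evaluation mode (dropout off,
    batch-norm running statistics)."""
    bundle.set_training(False)
    out = []
    for i in range(0, len(images), batch_size):
        feats = bundle.encoder.forward(images[i : i + batch_size])
        out.append(bundle.classifier.forward(feats))
    return np.concatenate(out, axis=0)


def predict_labels(bundle: ModelBundle, images: np.ndarray) -> list[str]:
    """Argmax labels; a tie goes to 'normal'."""
    probs = predict(bundle, images)
    return ["cardiomegaly" if p[1] > 0.5 else "normal" for p in probs]


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Persist all parameters and batch-norm statistics to a .npz file."""
    arrays = {}
    for cname, comp in bundle.components().items():
        for i, layer in enumerate(comp.iter_layers()):
            for pname, arr in layer.params.items():
                arrays[f"{cname}/{i}/{pname}"] = arr
            if isinstance(layer, nn.BatchNorm):
                arrays[f"{cname}/{i}/running_mean"] = layer.running_mean
                arrays[f"{cname}/{i}/running_var"] = layer.running_var
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_bundle(bundle: ModelBundle, path: str | Path) -> ModelBundle:
    """Load parameters saved by ``save_bundle`` into a same-shape bundle."""
    data = np.load(path)
    for cname, comp in bundle.components().items():
        for i, layer in enumerate(comp.iter_layers()):
            for pname in layer.params:
                layer.params[pname][...] = data[f"{cname}/{i}/{pname}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = data[f"{cname}/{i}/running_mean"]
                layer.running_var[...] = data[f"{cname}/{i}/running_var"]
    return bundle
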