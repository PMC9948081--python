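"""Training objectives of the adaptation framework.

Loss functions for the four components and their convex combination:

* weighted categorical cross-entropy ``L_C`` for the source classifier,
* binary cross-entropy ``L_D`` for the domain discriminator (source
  features labeled 1, target features labeled 0; a single 1/bs factor
  normalizes the sum over both domain halves),
* squared-error reconstruction loss ``L_R`` for the target decoder
  (per-sample squared L2 norm over all pixels and channels),
* inverted-label adversarial loss ``L_adv`` pushing target features toward
  the discriminator's source label,
* the encoder's combined loss ``lambda_c L_C + lambda_r L_R + lambda_d
  L_adv`` with convex coefficients.

Per-sample weights counteract class imbalance: a sample of the positive
class (cardiomegaly) is weighted by the negative-class fraction n-/n and
vice versa, so both classes contribute equal total weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7  # log clamp

#: One-hot convention: (1, 0) = normal (negative), (0, 1) = cardiomegaly (positive).
ONE_HOT = {"normal": (1.0, 0.0), "cardiomegaly": (0.0, 1.0)}


class ObjectiveError(ValueError):
    pass


@dataclass(frozen=True)
class LossWeights:
    """Convex coefficients of the encoder loss. ``lambda_d = 0`` recovers the
    reconstruction-only scheme (DRDA); the regularized scheme (RDRDA) uses
    0.45 / 0.45 / 0.1."""

    lambda_c: float = 0.5
    lambda_r: float = 0.5
    lambda_d: float = 0.0

    def validate(self) -> None:
        if min(self.lambda_c, self.lambda_r, self.lambda_d) < 0:
            raise ObjectiveError("loss weights must be nonnegative")
        total = self.lambda_c + self.lambda_r + self.lambda_d
        if abs(total - 1.0) > 1e-9:
            raise ObjectiveError(f"loss weights must sum to 1, got {total}")

    @classmethod
    def drda(cls) -> "LossWeights":
        return cls(0.5, 0.5, 0.0)

    @classmethod
    def rdrda(cls) -> "LossWeights":
        return cls(0.45, 0.45, 0.1)


def sample_weights(labels: np.ndarray) -> np.ndarray:
    """Imbalance weights from one-hot labels (n, 2).

    w = n-/n for positives, n+/n for negatives; both classes then carry the
    same summed weight n+ n- / n.  Raises if only one class is present.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 2 or labels.shape[1] != 2:
        raise ObjectiveError(f"labels must be one-hot of shape (n, 2), got {labels.shape}")
    pos = labels[:, 1] == 1.0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ObjectiveError("sample_weights needs both classes present")
    n = n_pos + n_neg
    return np.where(pos, n_neg / n, n_pos / n)


def classification_loss(predictions: np.ndarray, labels: np.ndarray,
                        weights: np.ndarray | None = None,
                        batch_size: int | None = None) -> float:
    """Weighted categorical cross-entropy, averaged over the batch."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ObjectiveError(f"shape mismatch: {predictions.shape} vs {labels.shape}")
    bs = batch_size if batch_size is not None else len(predictions)
    w = np.ones(len(predictions)) if weights is None else np.asarray(weights, dtype=float)
    ce = -(labels * np.log(np.clip(predictions, EPS, 1.0))).sum(axis=1)
    return float((w * ce).sum() / bs)


def discriminator_loss(d_source: np.ndarray, d_target: np.ndarray,
                       batch_size: int | None = None) -> float:
    """Binary cross-entropy over both domain halves with a single 1/bs factor."""
    d_source = np.asarray(d_source, dtype=float).reshape(-1)
    d_target = np.asarray(d_target, dtype=float).reshape(-1)
    for name, v in (("d_source", d_source), ("d_target", d_target)):
        if v.min() < 0.0 or v.max() > 1.0:
            raise ObjectiveError(f"{name} values outside [0, 1]")
    bs = batch_size if batch_size is not None else len(d_source)
    ls = np.log(np.clip(d_source, EPS, 1.0)).sum()
    lt = np.log(np.clip(1.0 - d_target, EPS, 1.0)).sum()
    return float(-(ls + lt) / bs)


def reconstruction_loss(targets: np.ndarray, reconstructions: np.ndarray,
                        batch_size: int | None = None,
                        per_pixel: bool = False) -> float:
    """Mean over the batch of per-sample squared L2 reconstruction error.

    The default sums squared residuals over all pixels and channels of each
    sample; ``per_pixel=True`` divides by the per-sample element count, which
    decouples the loss magnitude from image size.
    """
    targets = np.asarray(targets, dtype=float)
    reconstructions = np.asarray(reconstructions, dtype=float)
    if targets.shape != reconstructions.shape:
        raise ObjectiveError(f"shape mismatch: {targets.shape} vs {reconstructions.shape}")
    bs = batch_size if batch_size is not None else len(targets)
    res = (targets - reconstructions).reshape(len(targets), -1)
    per_sample = (res ** 2).sum(axis=1)
    if per_pixel:
        per_sample = per_sample / res.shape[1]
    return float(per_sample.sum() / bs)


def adversarial_loss(d_target: np.ndarray, batch_size: int | None = None) -> float:
    """Inverted-label loss: -mean log D(E(z)), minimized when the
    discriminator assigns target features the source label 1."""
    d_target = np.asarray(d_target, dtype=float).reshape(-1)
    bs = batch_size if batch_size is not None else len(d_target)
    return float(-np.log(np.clip(d_target, EPS, 1.0)).sum() / bs)


def combined_encoder_loss(lc: float, lr: float, ladv: float, weights: LossWeights) -> float:
    """Convex combination lambda_c * L_C + lambda_r * L_R + lambda_d * L_adv."""
    weights.validate()
    return weights.lambda_c * lc + weights.lambda_r * lr + weights.lambda_d * ladv


# --- gradients (with respect to the network outputs), used by the trainer ---

def classification_loss_grad(predictions, labels, weights, batch_size) -> np.ndarray:
    p = np.clip(predictions, EPS, 1.0)
    g = -(np.asarray(labels) / p) * np.asarray(weights)[:, None] / batch_size
    return np.where(predictions > EPS, g, 0.0)


def discriminator_loss_grads(d_source, d_target, batch_size):
    gs = -1.0 / np.clip(d_source, EPS, 1.0) / batch_size
    gt = 1.0 / np.clip(1.0 - d_target, EPS, 1.0) / batch_size
    return gs, gt


def reconstruction_loss_grad(targets, reconstructions, batch_size, per_pixel=False) -> np.ndarray:
    g = 2.0 * (reconstructions - targets) / batch_size
    if per_pixel:
        g = g / (targets[0].size)
    return g


def adversarial_loss_grad(d_target, batch_size) -> np.ndarray:
    return -1.0 / np.clip(d_target, EPS, 1.0) / batch_size
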