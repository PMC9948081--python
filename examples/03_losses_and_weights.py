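"""Imbalance weights and the training losses at closed-form points."""

import math

import numpy as np

from cxrda.objectives import (
    LossWeights,
    adversarial_loss,
    classification_loss,
    combined_encoder_loss,
    discriminator_loss,
    reconstruction_loss,
    sample_weights,
)

# Archive-scale class counts: 1712 cardiomegaly vs 6966 normal.
labels = np.concatenate([np.tile([0.0, 1.0], (1712, 1)),
                         np.tile([1.0, 0.0], (6966, 1))])
w = sample_weights(labels)
print(f"positive-sample weight n-/n = {w[0]:.5f}  (6966/8678 = {6966/8678:.5f})")
print(f"negative-sample weight n+/n = {w[-1]:.5f}  (1712/8678 = {1712/8678:.5f})")
pos = labels[:, 1] == 1
print(f"summed weight per class: {w[pos].sum():.2f} vs {w[~pos].sum():.2f} (equal)")

# Closed-form loss values.
lc = classification_loss(np.array([[0.5, 0.5]]), np.array([[0.0, 1.0]]))
print(f"\nuninformed classifier: L_C = {lc:.4f}  (ln 2 = {math.log(2):.4f})")
half = np.full(8, 0.5)
print(f"uninformed discriminator: L_D = {discriminator_loss(half, half, 8):.4f} "
      f"(2 ln 2 = {2 * math.log(2):.4f})")
print(f"fooled discriminator: L_adv = {adversarial_loss(np.full(8, 1 - 1e-7), 8):.2e}")
z = np.zeros((1, 2, 2, 1))
zhat = np.array([0.1, -0.1, 0.2, 0.0]).reshape(1, 2, 2, 1)
print(f"reconstruction residuals (0.1, -0.1, 0.2, 0): L_R = "
      f"{reconstruction_loss(z, z - zhat):.4f}")

# Convex combination driving the encoder.
print(f"\nDRDA combination (lambda_c = lambda_r = 0.5):  "
      f"{combined_encoder_loss(0.8, 0.2, 0.0, LossWeights.drda()):.3f}")
print(f"RDRDA combination (0.45/0.45/0.1) of unit losses: "
      f"{combined_encoder_loss(1.0, 1.0, 1.0, LossWeights.rdrda()):.3f}")
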