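"""Focal loss behaviour, class weighting and missing-label masking."""

import math

import numpy as np

from molfuse import (LossConfig, bce, classification_task_loss,
                     derive_class_weights, focal_loss, regression_task_loss)

print("BCE(0.5, y=1) =", round(float(bce(0.5, 1)), 4), "= ln 2")
print("focal(0.5, y=1, a=1, g=2) =", round(float(focal_loss(0.5, 1, 1.0, 2.0)), 5),
      "= 0.25 ln 2  (modulating factor (1-p)^2 = 0.25)")
print("focal(0.9, y=1, a=1, g=2) =", round(float(focal_loss(0.9, 1, 1.0, 2.0)), 5),
      " (well-classified example nearly silenced)")
print("gamma=0 recovers BCE:",
      np.allclose(focal_loss(np.r_[0.2, 0.5, 0.8], 1, 1.0, 0.0),
                  bce(np.r_[0.2, 0.5, 0.8], 1)))

# inverse-prevalence class weights on a 10%-positive endpoint
labels = (np.arange(100) < 10).astype(float)[:, None]
ap, an = derive_class_weights(labels, np.ones_like(labels, dtype=bool))
print(f"\n10% positive endpoint: alpha_pos={ap[0]:.2f}, alpha_neg={an[0]:.2f}")

# missing labels contribute nothing
p = np.array([[0.5, 0.99]])
y = np.array([[1.0, 0.0]])
observed = np.array([[True, False]])
loss = classification_task_loss(p, y, observed, LossConfig(beta=2.0))
print(f"masked task loss (one observed entry, beta=2): {loss:.5f}"
      f" = 2 * 0.25 ln 2 = {2 * 0.25 * math.log(2):.5f}")

print("regression MSE with beta=4:",
      regression_task_loss([1.0, -1.0], [0.0, 0.0], beta=4.0))
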