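"""Local focal / mean-squared-error losses with global task reweighting.

Classification endpoints use an alpha-weighted focal loss

    L_focal(p, y) = alpha * w_focal(p, y) * BCE(p, y),
    w_focal(p, y) = (1 - p)^gamma * y + p^gamma * (1 - y),

with focusing parameter gamma = 2 by default, so confidently correct
examples are down-weighted and hard ones emphasised; gamma = 0 and
alpha = 1 recover plain binary cross-entropy.  Regression tasks use the
squared error on the raw model output.  Each task loss is the mean over
*observed* (sample, endpoint) entries — missing labels are masked out
and contribute neither loss nor gradient — and is scaled by the global
dataset-balancing weight beta from the sampling schedule.

Class weights alpha are derived per endpoint by inverse prevalence:
with observed positive fraction q, positives get alpha = 1 - q and
negatives alpha = q, so the two classes contribute equally in
expectation.

Functions here operate on plain NumPy arrays and serve as the reference
API; ``focal_loss_graph`` / task-level graph losses mirror them on
autodiff tensors for training and are tested for elementwise agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad

logger = logging.getLogger(__name__)

EPS = 1e-7

__all__ = [
    "LossConfig", "bce", "focal_loss", "classification_task_loss",
    "regression_task_loss", "derive_class_weights",
    "classification_task_loss_graph", "regression_task_loss_graph",
]


@dataclass
class LossConfig:
    """Loss hyperparameters for one task."""

    gamma: float = 2.0
    alpha_pos: np.ndarray | float = 1.0  # per-endpoint weight applied to positives
    alpha_neg: np.ndarray | float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.beta < 1.0 - 1e-12:
            raise ValueError("beta must be >= 1")


def _clamp(p):
    return np.clip(p, EPS, 1.0 - EPS)


def bce(p, y):
    """Binary cross-entropy -[y log p + (1-y) log(1-p)] (p clamped)."""
    p = _clamp(np.asarray(p, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def focal_loss(p, y, alpha=1.0, gamma: float = 2.0):
    """alpha * [(1-p)^gamma y + p^gamma (1-y)] * BCE(p, y)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = _clamp(np.asarray(p, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    w = (1.0 - p) ** gamma * y + p ** gamma * (1.0 - y)
    return np.asarray(alpha) * w * bce(p, y)


def _alpha_matrix(y, cfg: LossConfig):
    ap = np.broadcast_to(np.asarray(cfg.alpha_pos, dtype=np.float64), y.shape)
    an = np.broadcast_to(np.asarray(cfg.alpha_neg, dtype=np.float64), y.shape)
    return ap * y + an * (1.0 - y)


def classification_task_loss(p, y, observed, cfg: LossConfig) -> float:
    """beta * mean over observed entries of the focal loss.

    Entries with ``observed=False`` contribute nothing; a batch with no
    observed entries yields 0 with a warning (no gradient step).
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    observed = np.asarray(observed, dtype=bool)
    if p.shape != y.shape or y.shape != observed.shape:
        raise ValueError("shape mismatch between predictions, labels and mask")
    n_obs = observed.sum()
    if n_obs == 0:
        logger.warning("classification batch with zero observed labels; loss = 0")
        return 0.0
    alpha = _alpha_matrix(y, cfg)
    # masked entries are made inert before the formula ever sees them
    per_entry = focal_loss(np.where(observed, p, 0.5), np.where(observed, y, 0.0),
                           np.where(observed, alpha, 0.0), cfg.gamma)
    return float(cfg.beta * per_entry.sum() / n_obs)


def regression_task_loss(z, y, beta: float = 1.0) -> float:
    """beta * mean squared error on raw outputs."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression loss inputs")
    return float(beta * np.mean((z - y) ** 2))


def derive_class_weights(labels, observed):
    """Inverse-prevalence class weights per endpoint.

    For endpoint k with observed positive fraction q_k, positives are
    weighted 1 - q_k and negatives q_k.  Endpoints observed in a single
    class fall back to 0.5/0.5 with a warning.

    Returns ``(alpha_pos, alpha_neg)`` arrays of length K.
    """
    labels = np.asarray(labels, dtype=np.float64)
    observed = np.asarray(observed, dtype=bool)
    K = labels.shape[1]
    alpha_pos = np.full(K, 0.5)
    alpha_neg = np.full(K, 0.5)
    for k in range(K):
        vals = labels[observed[:, k], k]
        if vals.size == 0 or len(np.unique(vals)) < 2:
            logger.warning("endpoint %d has a single observed class; alpha = 0.5/0.5", k)
            continue
        q = float(vals.mean())
        alpha_pos[k] = 1.0 - q
        alpha_neg[k] = q
    return alpha_pos, alpha_neg


# -- autodiff-graph versions (used by the training loop) ----------------

def classification_task_loss_graph(z: "ad.Tensor", y: np.ndarray, observed: np.ndarray,
                                   cfg: LossConfig) -> "ad.Tensor":
    """Graph version of :func:`classification_task_loss` on logits ``z``."""
    y = np.asarray(y, dtype=z.data.dtype)
    obs = np.asarray(observed, dtype=z.data.dtype)
    n_obs = obs.sum()
    if n_obs == 0:
        logger.warning("classification batch with zero observed labels; loss = 0")
        return ad.mul(ad.sum_(z), ad.Tensor(np.asarray(0.0, dtype=z.data.dtype)))
    p = ad.sigmoid(z)
    one = np.asarray(1.0, dtype=z.data.dtype)
    # clamp away from {0, 1} for finite logs
    p = ad.add(ad.mul(p, ad.Tensor(np.asarray(1.0 - 2 * EPS, dtype=z.data.dtype))),
               ad.Tensor(np.asarray(EPS, dtype=z.data.dtype)))
    log_p = ad.log(p)
    log_q = ad.log(ad.sub(ad.Tensor(one), p))
    bce_t = ad.sub(ad.Tensor(np.zeros_like(y)),
                   ad.add(ad.mul(ad.Tensor(y), log_p), ad.mul(ad.Tensor(1.0 - y), log_q)))
    w = ad.add(ad.mul(ad.power(ad.sub(ad.Tensor(one), p), cfg.gamma), ad.Tensor(y)),
               ad.mul(ad.power(p, cfg.gamma), ad.Tensor(1.0 - y)))
    alpha = _alpha_matrix(y, cfg).astype(z.data.dtype)
    per_entry = ad.mul(ad.mul(ad.Tensor(alpha * obs), w), bce_t)
    scale = np.asarray(cfg.beta / n_obs, dtype=z.data.dtype)
    return ad.mul(ad.sum_(per_entry), ad.Tensor(scale))


def regression_task_loss_graph(z: "ad.Tensor", y: np.ndarray, beta: float = 1.0) -> "ad.Tensor":
    """Graph version of :func:`regression_task_loss` on raw outputs."""
    y = np.asarray(y, dtype=z.data.dtype)
    diff = ad.sub(z, ad.Tensor(y))
    mse = ad.mean_(ad.mul(diff, diff))
    return ad.mul(mse, ad.Tensor(np.asarray(beta, dtype=z.data.dtype)))
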