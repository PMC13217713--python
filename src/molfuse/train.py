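"""Training orchestration: interleaved multitask, single-task and
head-only fine-tuning, with gradient accumulation, warmup and
checkpointing.

One "epoch" is ``sum_i b_i`` sampled batches (the schedule's total
batch count), so epoch counts are meaningful at any dataset scale.
Per optimizer step, ``grad_accum`` consecutive sampled batches
contribute averaged gradients (each batch loss is scaled by
1/grad_accum), so accumulation over equal-size batches is equivalent
to one larger batch when dropout is off.  The learning rate warms up
linearly over the first ``warmup_frac`` of optimizer steps and then
decays linearly to zero.  The optimizer is Adam with decoupled weight
decay; parameters frozen by the model's freezing schedule are never
touched.  Within a sampled task, batch contents come from a task-local
shuffled iterator that reshuffles each local pass.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .eval import evaluate_model
from .losses import (LossConfig, classification_task_loss_graph,
                     derive_class_weights, regression_task_loss_graph)
from .model import FusionModel, set_freezing
from .schedule import SamplingSchedule, compute_probabilities, draw_task
from .tokenize import encode, tokenize_ids

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TaskData", "tokenize_task", "AdamW", "lr_at",
           "train_multitask", "train_single_task", "fine_tune_heads",
           "pretrain_mlm"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    grad_accum: int = 2
    lr: float = 5e-5
    weight_decay: float = 5e-3
    epochs: int = 40
    warmup_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.warmup_frac < 1.0:
            raise ValueError("warmup_frac must be in [0, 1)")
        if self.batch_size < 1 or self.grad_accum < 1:
            raise ValueError("batch_size and grad_accum must be >= 1")

    @property
    def effective_batch(self) -> int:
        return self.batch_size * self.grad_accum


@dataclass
class TaskData:
    """Tokenized arrays for one task (training or evaluation side)."""

    spec: object  # needs .name/.kind/.n_endpoints/.requires_protein
    mol_ids: np.ndarray
    mol_mask: np.ndarray
    labels: np.ndarray
    observed: np.ndarray
    prot_tokens: list | None = None
    loss_cfg: LossConfig = field(default_factory=LossConfig)

    @property
    def n(self) -> int:
        return self.mol_ids.shape[0]


def tokenize_task(spec, records, mol_tok, max_len: int, prot_tok=None,
                  loss_cfg: LossConfig | None = None) -> TaskData:
    """Build a :class:`TaskData` from molecule or DTI records.

    Classification tasks derive inverse-prevalence class weights from
    the provided records unless an explicit loss config is given.
    """
    requires_protein = getattr(spec, "requires_protein", False)
    encoded = [encode(r.smiles, mol_tok, max_len) for r in records]
    ids = np.stack([ts.ids for ts in encoded])
    mask = np.stack([ts.attention_mask for ts in encoded])
    if requires_protein:
        if prot_tok is None:
            raise ValueError("protein tokenizer required for a DTI task")
        prot_tokens = [tokenize_ids(r.protein, prot_tok) for r in records]
        labels = np.array([[r.affinity] for r in records])
        observed = np.ones_like(labels, dtype=bool)
    else:
        prot_tokens = None
        labels = np.stack([r.labels for r in records])
        observed = np.stack([r.observed for r in records])
    if loss_cfg is None:
        if spec.kind == "classification":
            ap, an = derive_class_weights(labels, observed)
            loss_cfg = LossConfig(alpha_pos=ap, alpha_neg=an)
        else:
            loss_cfg = LossConfig()
    return TaskData(spec=spec, mol_ids=ids, mol_mask=mask, labels=labels,
                    observed=observed, prot_tokens=prot_tokens, loss_cfg=loss_cfg)


class AdamW:
    """Adam with decoupled weight decay; skips frozen parameters."""

    def __init__(self, named_params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.named_params = list(named_params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in self.named_params}
        self.v = {n: np.zeros_like(p.data) for n, p in self.named_params}

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        lr = self.lr * lr_scale
        for name, p in self.named_params:
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= (lr * (mhat / (np.sqrt(vhat) + self.eps))
                       + lr * self.wd * p.data).astype(p.data.dtype)

    def zero_grad(self):
        for _, p in self.named_params:
            p.grad = None


def lr_at(step: int, total_steps: int, warmup_frac: float) -> float:
    """Piecewise-linear schedule scale in [0, 1]: 0 -> peak -> 0."""
    warm = max(int(np.floor(warmup_frac * total_steps)), 1)
    if step < warm:
        return step / warm
    if total_steps <= warm:
        return 1.0
    return max(0.0, (total_steps - step) / (total_steps - warm))


class _BatchCycler:
    """Task-local shuffled batch iterator, reshuffled each local pass."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = min(batch_size, n)
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next_batch(self) -> np.ndarray:
        if self._pos + self.batch_size > self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        out = self._order[self._pos: self._pos + self.batch_size]
        self._pos += self.batch_size
        return out


def _task_loss_graph(model: FusionModel, data: TaskData, idx: np.ndarray,
                     beta: float):
    prot = [data.prot_tokens[i] for i in idx] if data.prot_tokens is not None else None
    z = model.forward_task(data.spec.name, data.mol_ids[idx], data.mol_mask[idx], prot)
    cfg = data.loss_cfg
    if data.spec.kind == "classification":
        cfg = LossConfig(gamma=cfg.gamma, alpha_pos=cfg.alpha_pos,
                         alpha_neg=cfg.alpha_neg, beta=beta)
        return classification_task_loss_graph(z, data.labels[idx], data.observed[idx], cfg)
    return regression_task_loss_graph(z, data.labels[idx], beta=beta)


def train_multitask(model: FusionModel, task_data: dict, schedule: SamplingSchedule,
                    cfg: TrainConfig, eval_data: dict | None = None,
                    checkpoint_dir: str | None = None):
    """Interleaved multitask training; returns ``(model, log)``.

    ``log`` is a list of per-epoch dicts with mean sampled-batch loss
    per task and, when ``eval_data`` is given, per-task metrics.
    """
    missing = set(schedule.task_names) - set(task_data)
    if missing:
        raise ValueError(f"schedule references tasks without data: {missing}")
    rng = np.random.default_rng(cfg.seed)
    model.train_mode(seed=cfg.seed + 1)
    opt = AdamW(model.named_parameters(), cfg.lr, cfg.weight_decay)

    betas = {name: schedule.beta(name) for name in schedule.task_names}
    cyclers = {
        name: _BatchCycler(task_data[name].n, cfg.batch_size,
                           np.random.default_rng(cfg.seed + 17 + i))
        for i, name in enumerate(schedule.task_names)
    }

    draws_per_epoch = schedule.draws_per_epoch
    total_draws = cfg.epochs * draws_per_epoch
    total_steps = ceil(total_draws / cfg.grad_accum)
    inv_accum = Tensor(np.float32(1.0 / cfg.grad_accum))

    log = []
    opt_step = 0
    accum = 0
    for epoch in range(cfg.epochs):
        epoch_losses: dict = {}
        for _ in range(draws_per_epoch):
            t_idx = draw_task(schedule, rng)
            name = schedule.task_names[t_idx]
            data = task_data[name]
            idx = cyclers[name].next_batch()
            loss = ad.mul(_task_loss_graph(model, data, idx, betas[name]), inv_accum)
            value = float(loss.data) * cfg.grad_accum
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite loss on task {name!r} at epoch {epoch}")
            loss.backward()
            epoch_losses.setdefault(name, []).append(value)
            accum += 1
            if accum == cfg.grad_accum:
                opt.step(lr_scale=lr_at(opt_step, total_steps, cfg.warmup_frac))
                opt.zero_grad()
                opt_step += 1
                accum = 0
        if accum:  # flush a trailing partial accumulation window
            opt.step(lr_scale=lr_at(opt_step, total_steps, cfg.warmup_frac))
            opt.zero_grad()
            opt_step += 1
            accum = 0
        entry = {"epoch": epoch,
                 "loss": {k: float(np.mean(v)) for k, v in epoch_losses.items()}}
        if eval_data is not None:
            reports = evaluate_model(model, eval_data)
            entry["metrics"] = {k: (r.metric, r.value) for k, r in reports.items()}
            model.train_mode()
        log.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
        if checkpoint_dir is not None:
            model.save(checkpoint_dir)
    model.eval_mode()
    return model, log


def _one_task_schedule(name: str, n_train: int, cfg: TrainConfig) -> SamplingSchedule:
    b = ceil(n_train / cfg.batch_size)
    return SamplingSchedule([name], [n_train], [b], compute_probabilities([b]))


def train_single_task(model: FusionModel, task_data: TaskData, cfg: TrainConfig,
                      eval_data: dict | None = None):
    """Single-task training: same machinery with pi = 1 and beta = 1."""
    name = task_data.spec.name
    schedule = _one_task_schedule(name, task_data.n, cfg)
    assert schedule.beta(name) == 1.0
    return train_multitask(model, {name: task_data}, schedule, cfg, eval_data=eval_data)


def fine_tune_heads(model: FusionModel, new_task_data: dict, cfg: TrainConfig,
                    eval_data: dict | None = None):
    """Attach fresh heads for new tasks and train only those heads.

    Encoders, shared layer and existing heads stay bit-identical; a new
    task name colliding with an existing head is a config error.
    Returns ``(model, log)``.
    """
    for name in new_task_data:
        if name in model.tasks:
            raise ValueError(f"task {name!r} already has a head")
    for name, data in new_task_data.items():
        # stable per-task seed (str hash is process-randomized)
        offset = zlib.crc32(name.encode()) % 1000
        model.add_task(data.spec, seed=cfg.seed + offset)
    set_freezing(model, mode="head_tune")
    new_head_names = set()
    for name in new_task_data:
        h1, h2 = model.heads[name]
        new_head_names |= {n for n, _ in h1.params(f"head.{name}.fc1")}
        new_head_names |= {n for n, _ in h2.params(f"head.{name}.fc2")}
    for pname, p in model.named_parameters():
        p.requires_grad = pname in new_head_names

    names = sorted(new_task_data)
    sizes = [new_task_data[n].n for n in names]
    counts = [ceil(s / cfg.batch_size) for s in sizes]
    schedule = SamplingSchedule(names, sizes, counts, compute_probabilities(counts))
    return train_multitask(model, new_task_data, schedule, cfg, eval_data=eval_data)


def pretrain_mlm(model: FusionModel, encoder: str, sequences, cfg: TrainConfig,
                 rate: float = 0.15):
    """Toy-scale masked-language-model pretraining of one encoder.

    ``sequences`` is a list of :class:`~molfuse.tokenize.TokenizedSequence`.
    15% of non-special tokens per sequence are masked and reconstructed
    through an output projection tied to the token embedding table.
    Returns the per-epoch mean cross-entropy list.
    """
    from .tokenize import mlm_mask

    enc = model.mol_encoder if encoder == "mol" else model.prot_encoder
    V = enc.tok_emb.shape[0]
    rng = np.random.default_rng(cfg.seed)
    model.train_mode(seed=cfg.seed + 1)
    opt = AdamW(model.named_parameters(), cfg.lr, cfg.weight_decay)
    n = len(sequences)
    steps_per_epoch = ceil(n / cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    history = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            batch = [sequences[i] for i in order[lo: lo + cfg.batch_size]]
            masked, targets, tmask = mlm_mask(batch, rate=rate,
                                              rng_seed=int(rng.integers(2 ** 31)))
            if not tmask.any():
                continue
            att = np.stack([ts.attention_mask for ts in batch])
            logits = model.mlm_logits(encoder, masked, att)
            probs = ad.softmax(logits, axis=-1)
            onehot = np.zeros(logits.shape, dtype=np.float32)
            rr, cc = np.nonzero(tmask)
            onehot[rr, cc, targets[rr, cc]] = 1.0
            nll = ad.mul(ad.log(ad.add(probs, Tensor(np.float32(1e-9)))),
                         Tensor(-onehot))
            loss = ad.mul(ad.sum_(nll), Tensor(np.float32(1.0 / len(rr))))
            losses.append(float(loss.data))
            loss.backward()
            opt.step(lr_scale=lr_at(step, total_steps, cfg.warmup_frac))
            opt.zero_grad()
            step += 1
        history.append(float(np.mean(losses)))
    model.eval_mode()
    return history
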