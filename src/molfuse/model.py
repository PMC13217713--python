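"""Dual sequence-encoder fusion model with per-task heads.

Two transformer encoders — one over SMILES tokens, one over protein
tokens — are fused at the [CLS] level: the molecule [CLS] vector is
concatenated with two protein [CLS] vectors (the protein encoder is
applied twice, once per 512-token segment, sharing weights, so
sequences of up to 1024 tokens are covered at half the attention
cost).  Molecule-only inputs substitute exact zero vectors for the two
protein blocks, so every input yields a fused vector of length
``H_mol + 2 * H_prot`` (2304 at the default hidden size 768).  The
fused vector passes through a shared representation layer (fully
connected, tanh, dropout) and is routed to the head of the sampled
task; each head is a two-layer MLP with tanh and dropout 0.1 whose
output width equals the task's endpoint count.

Encoders are pre-norm transformers with learned absolute position
embeddings, GELU feed-forwards and dropout 0.1.  Partial freezing
treats the embedding tables plus the first k layers as one frozen
group (default k = 4 of 6), leaving the last layers trainable;
``head_tune`` mode freezes both encoders and the shared layer
entirely.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

logger = logging.getLogger(__name__)

__all__ = ["EncoderConfig", "TransformerEncoder", "FusionModel", "build_model",
           "set_freezing"]


@dataclass
class EncoderConfig:
    vocab_size: int
    n_layers: int = 6
    n_heads: int = 12
    hidden: int = 768
    max_len: int = 512
    ffn_mult: int = 4
    dropout: float = 0.1
    freeze_first_k: int = 4

    def __post_init__(self):
        if self.hidden % self.n_heads:
            raise ValueError("hidden size must be divisible by n_heads")
        if not 0 <= self.freeze_first_k <= self.n_layers:
            raise ValueError("freeze_first_k must be in [0, n_layers]")


# init scale chosen for training from scratch at small width; colder
# BERT-style 0.02 inits under-excite attention in a 2-layer toy model
def _param(rng, shape, std=0.05):
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


def _zeros(shape):
    return Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)


def _ones(shape):
    return Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)


class _Linear:
    def __init__(self, rng, d_in, d_out):
        self.W = _param(rng, (d_in, d_out))
        self.b = _zeros((d_out,))

    def __call__(self, x):
        return ad.add(ad.matmul(x, self.W), self.b)

    def params(self, prefix):
        return [(f"{prefix}.W", self.W), (f"{prefix}.b", self.b)]


class _LayerNorm:
    def __init__(self, d):
        self.g = _ones((d,))
        self.b = _zeros((d,))

    def __call__(self, x):
        return ad.add(ad.mul(ad.layer_norm(x), self.g), self.b)

    def params(self, prefix):
        return [(f"{prefix}.g", self.g), (f"{prefix}.b", self.b)]


class _EncoderLayer:
    """Pre-norm transformer layer: x + MHA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, rng, cfg: EncoderConfig):
        H = cfg.hidden
        self.cfg = cfg
        self.ln1 = _LayerNorm(H)
        self.wq = _Linear(rng, H, H)
        self.wk = _Linear(rng, H, H)
        self.wv = _Linear(rng, H, H)
        self.wo = _Linear(rng, H, H)
        self.ln2 = _LayerNorm(H)
        self.ff1 = _Linear(rng, H, cfg.ffn_mult * H)
        self.ff2 = _Linear(rng, cfg.ffn_mult * H, H)

    def __call__(self, x, attn_bias, dropout_fn):
        cfg = self.cfg
        B, T, H = x.shape
        nh, dh = cfg.n_heads, H // cfg.n_heads

        h = self.ln1(x)
        def split(t):
            return ad.transpose(ad.reshape(t, (B, T, nh, dh)), (0, 2, 1, 3))
        q, k, v = split(self.wq(h)), split(self.wk(h)), split(self.wv(h))
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))),
                        Tensor(np.float32(1.0 / np.sqrt(dh))))
        scores = ad.add(scores, Tensor(attn_bias))
        attn = ad.softmax(scores, axis=-1)
        ctx = ad.matmul(attn, v)
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (B, T, H))
        x = ad.add(x, dropout_fn(self.wo(ctx)))

        h = self.ln2(x)
        h = self.ff2(ad.gelu(self.ff1(h)))
        return ad.add(x, dropout_fn(h))

    def params(self, prefix):
        out = []
        for name, mod in (("ln1", self.ln1), ("wq", self.wq), ("wk", self.wk),
                          ("wv", self.wv), ("wo", self.wo), ("ln2", self.ln2),
                          ("ff1", self.ff1), ("ff2", self.ff2)):
            out += mod.params(f"{prefix}.{name}")
        return out


class TransformerEncoder:
    """Token + position embeddings, pre-norm layers, final layer norm."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.tok_emb = _param(rng, (cfg.vocab_size, cfg.hidden))
        self.pos_emb = _param(rng, (cfg.max_len, cfg.hidden))
        self.layers = [_EncoderLayer(rng, cfg) for _ in range(cfg.n_layers)]
        self.final_ln = _LayerNorm(cfg.hidden)

    def forward(self, ids: np.ndarray, mask: np.ndarray, dropout_fn):
        """ids, mask: (B, T) -> final hidden states (B, T, H)."""
        B, T = ids.shape
        if T > self.cfg.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.cfg.max_len}")
        x = ad.add(ad.embedding(self.tok_emb, ids),
                   ad.embedding(self.pos_emb, np.broadcast_to(np.arange(T), (B, T))))
        x = dropout_fn(x)
        bias = ((1.0 - mask.astype(np.float32)) * np.float32(-1e9))[:, None, None, :]
        for layer in self.layers:
            x = layer(x, bias, dropout_fn)
        return self.final_ln(x)

    def params(self, prefix):
        out = [(f"{prefix}.tok_emb", self.tok_emb), (f"{prefix}.pos_emb", self.pos_emb)]
        for i, layer in enumerate(self.layers):
            out += layer.params(f"{prefix}.layers.{i}")
        out += self.final_ln.params(f"{prefix}.final_ln")
        return out

    def frozen_param_names(self, prefix, k: int):
        """Names in the frozen group: embeddings + first k layers."""
        names = {f"{prefix}.tok_emb", f"{prefix}.pos_emb"}
        for i in range(k):
            names |= {n for n, _ in self.layers[i].params(f"{prefix}.layers.{i}")}
        return names


@dataclass(frozen=True)
class ModelTask:
    name: str
    kind: str  # classification | regression
    n_endpoints: int
    requires_protein: bool = False


class FusionModel:
    def __init__(self, mol_cfg: EncoderConfig, prot_cfg: EncoderConfig,
                 tasks, shared_dim: int | None = None, seed: int = 0):
        names = [t.name for t in tasks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate task names")
        if not tasks:
            raise ValueError("at least one task required")
        rng = np.random.default_rng(seed)
        self.mol_cfg, self.prot_cfg = mol_cfg, prot_cfg
        self.tasks = {t.name: ModelTask(t.name, t.kind, t.n_endpoints,
                                        getattr(t, "requires_protein", False))
                      for t in tasks}
        self.mol_encoder = TransformerEncoder(mol_cfg, rng)
        self.prot_encoder = TransformerEncoder(prot_cfg, rng)
        self.fused_dim = mol_cfg.hidden + 2 * prot_cfg.hidden
        self.shared_dim = shared_dim or mol_cfg.hidden
        self.shared = _Linear(rng, self.fused_dim, self.shared_dim)
        self.heads = {}
        for t in self.tasks.values():
            self.heads[t.name] = (_Linear(rng, self.shared_dim, self.shared_dim),
                                  _Linear(rng, self.shared_dim, t.n_endpoints))
        self.dropout = mol_cfg.dropout
        self.training = False
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- modes ----------------------------------------------------------
    def train_mode(self, seed: int | None = None):
        self.training = True
        if seed is not None:
            self._dropout_rng = np.random.default_rng(seed)

    def eval_mode(self):
        self.training = False

    def _dropout(self, x):
        if not self.training or self.dropout <= 0:
            return x
        keep = 1.0 - self.dropout
        mask = (self._dropout_rng.random(x.shape) < keep).astype(np.float32) / np.float32(keep)
        return ad.mul(x, Tensor(mask))

    # -- parameters ------------------------------------------------------
    def named_parameters(self):
        out = self.mol_encoder.params("mol") + self.prot_encoder.params("prot")
        out += self.shared.params("shared")
        for name, (h1, h2) in self.heads.items():
            out += h1.params(f"head.{name}.fc1") + h2.params(f"head.{name}.fc2")
        return out

    def add_task(self, spec, seed: int = 0):
        """Register a new task with a freshly initialised head."""
        if spec.name in self.tasks:
            raise ValueError(f"task {spec.name!r} already registered")
        rng = np.random.default_rng(seed)
        task = ModelTask(spec.name, spec.kind, spec.n_endpoints,
                         getattr(spec, "requires_protein", False))
        self.tasks[task.name] = task
        self.heads[task.name] = (_Linear(rng, self.shared_dim, self.shared_dim),
                                 _Linear(rng, self.shared_dim, task.n_endpoints))

    def head_output_width(self) -> int:
        return sum(t.n_endpoints for t in self.tasks.values())

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(p.data.size for _, p in self.named_parameters()
                   if p.requires_grad or not trainable_only)

    # -- forward pieces --------------------------------------------------
    def encode_molecule(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """(B, T) token ids/mask -> molecule [CLS] vectors (B, H_mol)."""
        h = self.mol_encoder.forward(ids, mask, self._dropout)
        return ad.take_position(h, 0)

    def encode_protein_two_segments(self, token_lists):
        """Raw protein token id lists -> two [CLS] vectors (B, H_prot) each.

        The raw stream is split at the segment capacity (max_len - 2);
        each segment gets its own [CLS]/[SEP] framing and passes through
        the *same* encoder weights.  A segment with no real tokens
        yields the exact zero vector.  Streams longer than two segments
        are truncated with a warning.
        """
        from .tokenize import CLS_ID, PAD_ID, SEP_ID

        cap = self.prot_cfg.max_len - 2
        B = len(token_lists)
        outs = []
        for seg_idx in range(2):
            ids = np.full((B, self.prot_cfg.max_len), PAD_ID, dtype=np.int64)
            mask = np.zeros((B, self.prot_cfg.max_len), dtype=np.int64)
            nonempty = np.zeros((B, 1), dtype=np.float32)
            for r, toks in enumerate(token_lists):
                if len(toks) > 2 * cap and seg_idx == 0:
                    logger.warning("protein token stream of length %d truncated to %d",
                                   len(toks), 2 * cap)
                seg = list(toks[seg_idx * cap:(seg_idx + 1) * cap])
                framed = [CLS_ID] + seg + [SEP_ID]
                ids[r, :len(framed)] = framed
                mask[r, :len(framed)] = 1
                nonempty[r, 0] = 1.0 if seg else 0.0
            h = self.prot_encoder.forward(ids, mask, self._dropout)
            cls = ad.take_position(h, 0)
            outs.append(ad.mul(cls, Tensor(nonempty)))
        return outs[0], outs[1]

    def fuse(self, mol_cls: Tensor, prot_pair=None) -> Tensor:
        """Concatenate [mol | prot1 | prot2]; absent protein -> zero blocks."""
        B = mol_cls.shape[0]
        if prot_pair is None:
            zero = Tensor(np.zeros((B, self.prot_cfg.hidden), dtype=mol_cls.data.dtype))
            prot_pair = (zero, zero)
        return ad.concat([mol_cls, prot_pair[0], prot_pair[1]], axis=-1)

    def forward_fused(self, fused: Tensor, task_name: str) -> Tensor:
        shared = self._dropout(ad.tanh(self.shared(fused)))
        h1, h2 = self.heads[task_name]
        h = self._dropout(ad.tanh(h1(shared)))
        return h2(h)

    def forward_task(self, task_name: str, mol_ids: np.ndarray, mol_mask: np.ndarray,
                     prot_tokens=None) -> Tensor:
        """Full forward for one task batch -> (B, K) raw outputs (logits
        for classification, direct values for regression)."""
        task = self.tasks.get(task_name)
        if task is None:
            raise KeyError(f"unknown task {task_name!r}")
        if task.requires_protein and prot_tokens is None:
            raise ValueError(f"task {task_name!r} requires protein input")
        mol_cls = self.encode_molecule(mol_ids, mol_mask)
        prot_pair = None
        if task.requires_protein:
            prot_pair = self.encode_protein_two_segments(prot_tokens)
        fused = self.fuse(mol_cls, prot_pair)
        return self.forward_fused(fused, task_name)

    def mlm_logits(self, encoder: str, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """Masked-language-model logits with the output projection tied to
        the token embedding table: (B, T, V)."""
        enc = self.mol_encoder if encoder == "mol" else self.prot_encoder
        h = enc.forward(ids, mask, self._dropout)
        V, H = enc.tok_emb.shape
        flat = ad.reshape(h, (-1, H))
        logits = ad.matmul(flat, ad.transpose(enc.tok_emb, (1, 0)))
        return ad.reshape(logits, (ids.shape[0], ids.shape[1], V))

    # -- persistence -----------------------------------------------------
    def save(self, directory: str):
        os.makedirs(directory, exist_ok=True)
        cfg = {
            "mol_cfg": asdict(self.mol_cfg), "prot_cfg": asdict(self.prot_cfg),
            "shared_dim": self.shared_dim,
            "tasks": [asdict(t) for t in self.tasks.values()],
        }
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(cfg, fh, indent=1)
        np.savez(os.path.join(directory, "weights.npz"),
                 **{name: p.data for name, p in self.named_parameters()})

    @classmethod
    def load(cls, directory: str) -> "FusionModel":
        with open(os.path.join(directory, "config.json")) as fh:
            cfg = json.load(fh)
        tasks = [ModelTask(**t) for t in cfg["tasks"]]
        model = cls(EncoderConfig(**cfg["mol_cfg"]), EncoderConfig(**cfg["prot_cfg"]),
                    tasks, shared_dim=cfg["shared_dim"])
        weights = np.load(os.path.join(directory, "weights.npz"))
        for name, p in model.named_parameters():
            p.data = weights[name].copy()
        return model


def build_model(mol_cfg: EncoderConfig, prot_cfg: EncoderConfig, tasks,
                shared_dim: int | None = None, seed: int = 0) -> FusionModel:
    """Construct a :class:`FusionModel` and apply the default (mtl)
    partial-freezing schedule from the encoder configs."""
    model = FusionModel(mol_cfg, prot_cfg, tasks, shared_dim=shared_dim, seed=seed)
    set_freezing(model, mode="mtl")
    return model


def set_freezing(model: FusionModel, mode: str = "mtl",
                 mol_freeze_k: int | None = None,
                 prot_freeze_k: int | None = None) -> FusionModel:
    """Apply a freezing schedule.

    ``mtl``/``stl``: freeze embeddings + first k layers of each encoder
    (k from each config unless overridden).  ``head_tune``: freeze both
    encoders fully and the shared layer; only heads train.
    """
    if mode not in ("mtl", "stl", "head_tune"):
        raise ValueError(f"unknown mode {mode!r}")
    for _, p in model.named_parameters():
        p.requires_grad = True
    if mode == "head_tune":
        frozen = {n for n, _ in model.mol_encoder.params("mol")}
        frozen |= {n for n, _ in model.prot_encoder.params("prot")}
        frozen |= {n for n, _ in model.shared.params("shared")}
    else:
        k_mol = model.mol_cfg.freeze_first_k if mol_freeze_k is None else mol_freeze_k
        k_prot = model.prot_cfg.freeze_first_k if prot_freeze_k is None else prot_freeze_k
        frozen = model.mol_encoder.frozen_param_names("mol", k_mol)
        frozen |= model.prot_encoder.frozen_param_names("prot", k_prot)
    for name, p in model.named_parameters():
        if name in frozen:
            p.requires_grad = False
    return model
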