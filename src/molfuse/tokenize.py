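"""Byte-level BPE tokenization for SMILES and protein corpora.

A byte-level byte-pair-encoding tokenizer trained by iteratively merging
the most frequent adjacent byte pair until a vocabulary limit is reached
or no candidate pair clears a frequency threshold.  Starting from the
raw 256-byte alphabet makes every string tokenizable and the
encode/decode round trip lossless.

Special tokens occupy the reserved low ids (pad=0, cls=1, sep=2,
mask=3) so that zero-padding of both ids and attention masks is
literally "padding with zeros".  Ties between equally frequent pairs
are broken lexicographically on the pair's byte strings, which makes
training deterministic.

Presets mirror the corpus-scale configurations used for chemical and
protein vocabularies: SMILES (vocab limit 4096, min pair frequency
500) and proteins (vocab limit 8192, min pair frequency 10000).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TokenizerModel", "TokenizedSequence", "train_bpe", "encode", "decode",
    "tokenize_ids", "mlm_mask", "SMILES_BPE_PRESET", "PROTEIN_BPE_PRESET",
    "PAD_ID", "CLS_ID", "SEP_ID", "MASK_ID",
]

PAD_ID, CLS_ID, SEP_ID, MASK_ID = 0, 1, 2, 3
_N_SPECIAL = 4
_BYTE_OFFSET = _N_SPECIAL  # byte b -> id b + 4

SMILES_BPE_PRESET = {"vocab_limit": 4096, "min_pair_freq": 500}
PROTEIN_BPE_PRESET = {"vocab_limit": 8192, "min_pair_freq": 10000}


@dataclass
class TokenizerModel:
    """A trained byte-level BPE model.

    ``id_to_bytes`` maps every non-special token id to the byte string
    it spells; merges are stored in training order as id pairs.
    """

    merges: list = field(default_factory=list)  # [(id_a, id_b, new_id), ...]
    id_to_bytes: dict = field(default_factory=dict)
    vocab_limit: int = 0
    min_pair_freq: int = 1

    def __post_init__(self):
        if not self.id_to_bytes:
            self.id_to_bytes = {b + _BYTE_OFFSET: bytes([b]) for b in range(256)}

    @property
    def vocab_size(self) -> int:
        return _N_SPECIAL + len(self.id_to_bytes)

    @property
    def pad_id(self) -> int:
        return PAD_ID

    @property
    def cls_id(self) -> int:
        return CLS_ID

    @property
    def sep_id(self) -> int:
        return SEP_ID

    @property
    def mask_id(self) -> int:
        return MASK_ID

    # -- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        obj = {
            "vocab_limit": self.vocab_limit,
            "min_pair_freq": self.min_pair_freq,
            "specials": {"pad": PAD_ID, "cls": CLS_ID, "sep": SEP_ID, "mask": MASK_ID},
            "merges": [[a, b, n] for a, b, n in self.merges],
            "vocab": {str(i): tok.hex() for i, tok in self.id_to_bytes.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path: str) -> "TokenizerModel":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        tok = cls(
            merges=[tuple(m) for m in obj["merges"]],
            id_to_bytes={int(i): bytes.fromhex(h) for i, h in obj["vocab"].items()},
            vocab_limit=obj["vocab_limit"],
            min_pair_freq=obj["min_pair_freq"],
        )
        return tok


@dataclass
class TokenizedSequence:
    """Fixed-length padded token ids with an attention mask."""

    ids: np.ndarray
    attention_mask: np.ndarray

    def __post_init__(self):
        assert self.ids.shape == self.attention_mask.shape
        assert np.all(self.ids[self.attention_mask == 0] == PAD_ID)

    @property
    def n_real(self) -> int:
        return int(self.attention_mask.sum())


def train_bpe(corpus, vocab_limit: int, min_pair_freq: int = 1) -> TokenizerModel:
    """Train byte-level BPE by greedy highest-frequency pair merging.

    Merging halts when the vocabulary reaches ``vocab_limit`` (counting
    the 4 specials and 256 base bytes) or when the best candidate pair
    occurs fewer than ``min_pair_freq`` times, whichever comes first.
    Equal-frequency ties resolve lexicographically on the pair's byte
    strings.
    """
    seqs = [list(s.encode("utf-8")) for s in corpus]
    if not seqs:
        raise ValueError("empty corpus: BPE training needs at least one sequence")
    if vocab_limit <= _N_SPECIAL + 256:
        tok = TokenizerModel(vocab_limit=vocab_limit, min_pair_freq=min_pair_freq)
        return tok
    if min_pair_freq < 1:
        raise ValueError("min_pair_freq must be >= 1")

    tok = TokenizerModel(vocab_limit=vocab_limit, min_pair_freq=min_pair_freq)
    seqs = [[b + _BYTE_OFFSET for b in s] for s in seqs]
    next_id = _BYTE_OFFSET + 256

    while tok.vocab_size < vocab_limit:
        counts: dict = {}
        for s in seqs:
            for a, b in zip(s, s[1:]):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        if not counts:
            break
        best_freq = max(counts.values())
        if best_freq < min_pair_freq:
            break
        best = min(
            (p for p, c in counts.items() if c == best_freq),
            key=lambda p: (tok.id_to_bytes[p[0]], tok.id_to_bytes[p[1]]),
        )
        a, b = best
        tok.id_to_bytes[next_id] = tok.id_to_bytes[a] + tok.id_to_bytes[b]
        tok.merges.append((a, b, next_id))
        new_seqs = []
        for s in seqs:
            out, i = [], 0
            while i < len(s):
                if i + 1 < len(s) and s[i] == a and s[i + 1] == b:
                    out.append(next_id)
                    i += 2
                else:
                    out.append(s[i])
                    i += 1
            new_seqs.append(out)
        seqs = new_seqs
        next_id += 1

    return tok


def tokenize_ids(seq: str, tok: TokenizerModel) -> list:
    """BPE-tokenize a string to raw token ids (no specials, no padding)."""
    if not seq:
        raise ValueError("cannot tokenize an empty sequence")
    ids = [b + _BYTE_OFFSET for b in seq.encode("utf-8")]
    for a, b, new in tok.merges:
        out, i = [], 0
        while i < len(ids):
            if i + 1 < len(ids) and ids[i] == a and ids[i + 1] == b:
                out.append(new)
                i += 2
            else:
                out.append(ids[i])
                i += 1
        ids = out
    return ids


def encode(seq: str, tok: TokenizerModel, max_len: int = 512) -> TokenizedSequence:
    """Encode to exactly ``max_len`` ids: [CLS] tokens [SEP] + zero padding.

    Sequences longer than ``max_len - 2`` tokens are truncated; the
    separator is always retained as the last real token.
    """
    body = tokenize_ids(seq, tok)
    body = body[: max_len - 2]
    ids = [CLS_ID] + body + [SEP_ID]
    mask = [1] * len(ids)
    pad = max_len - len(ids)
    ids = np.asarray(ids + [PAD_ID] * pad, dtype=np.int64)
    mask = np.asarray(mask + [0] * pad, dtype=np.int64)
    return TokenizedSequence(ids=ids, attention_mask=mask)


def decode(ts: TokenizedSequence | np.ndarray, tok: TokenizerModel) -> str:
    """Invert :func:`encode` (specials and padding stripped)."""
    ids = ts.ids if isinstance(ts, TokenizedSequence) else np.asarray(ts)
    parts = [tok.id_to_bytes[int(i)] for i in ids if int(i) >= _BYTE_OFFSET]
    return b"".join(parts).decode("utf-8")


def mlm_mask(batch, rate: float = 0.15, rng_seed: int = 0):
    """Select masked-language-model positions and build reconstruction targets.

    Per sequence, exactly ``round_half_up(rate * n_maskable)`` positions
    are drawn uniformly without replacement among non-special, non-pad
    positions and replaced by the mask id.  Returns ``(masked_ids,
    targets, target_mask)`` where targets hold the original ids at
    selected positions (and -1 elsewhere).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mask rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(rng_seed)
    ids = np.stack([ts.ids for ts in batch])
    masks = np.stack([ts.attention_mask for ts in batch])
    masked = ids.copy()
    targets = np.full_like(ids, -1)
    target_mask = np.zeros_like(ids, dtype=bool)
    for r in range(ids.shape[0]):
        eligible = np.where((masks[r] == 1) & (ids[r] >= _BYTE_OFFSET))[0]
        k = math.floor(rate * len(eligible) + 0.5)
        if k == 0:
            continue
        chosen = rng.choice(eligible, size=k, replace=False)
        targets[r, chosen] = ids[r, chosen]
        masked[r, chosen] = MASK_ID
        target_mask[r, chosen] = True
    return masked, targets, target_mask
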