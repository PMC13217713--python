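"""Train/test partitioning: stratified, random, scaffold-aware and k-fold.

Conventions: an 80/20 split puts exactly ``floor(0.8 n)`` records in
train; the k-fold split used for affinity benchmarks holds out one fold
(sizes within one of each other), giving a train side of
``floor((k-1) n / k)``.  All labels of a given compound (identical
canonical SMILES) are kept on one side of molecule-table splits, so
multi-endpoint datasets cannot leak a compound across the partition.

Scaffold splits group compounds by their generic Bemis–Murcko scaffold
(no stereo) and assign whole groups, largest first, until the train
fraction is reached — the deterministic convention popularised by the
MoleculeNet benchmarks.  Because scaffold test sets concentrate unseen
chemotypes they can shift the property distribution; the
:func:`split_shift_report` diagnostic quantifies this with molecular
weight summaries and a two-sample Kolmogorov–Smirnov distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SplitAssignment", "stratified_split", "random_split", "scaffold_split",
    "dti_fold_split", "split_shift_report",
]


@dataclass
class SplitAssignment:
    train: np.ndarray
    test: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self):
        self.train = np.asarray(sorted(self.train), dtype=np.int64)
        self.test = np.asarray(sorted(self.test), dtype=np.int64)
        if set(self.train) & set(self.test):
            raise ValueError("train and test overlap")


def _compound_groups(records):
    """Indices grouped by canonical SMILES, in first-appearance order."""
    groups: dict = {}
    for i, rec in enumerate(records):
        groups.setdefault(rec.smiles, []).append(i)
    return list(groups.values())


def _fill_train(groups, n_total: int, train_frac: float):
    target = int(np.floor(train_frac * n_total))
    train, test, filled = [], [], 0
    for g in groups:
        if filled < target:
            train.extend(g)
            filled += len(g)
        else:
            test.extend(g)
    return train, test


def random_split(records, train_frac: float = 0.8, seed: int = 0) -> SplitAssignment:
    """Uniform compound-grouped split with |train| = floor(train_frac * n)."""
    groups = _compound_groups(records)
    rng = np.random.default_rng(seed)
    rng.shuffle(groups)
    train, test = _fill_train(groups, len(records), train_frac)
    return SplitAssignment(train, test, "random", seed)


def stratified_split(records, train_frac: float = 0.8, seed: int = 0) -> SplitAssignment:
    """Class-balanced compound-grouped split for classification tables.

    Stratifies on the first endpoint observed in both classes (exact
    multi-label stratification is NP-hard); per-stratum train counts are
    floored, then topped up so |train| = floor(train_frac * n) overall.
    Endpoints with a single observed class are warned about and ignored
    for stratification.
    """
    labels = np.stack([r.labels for r in records])
    observed = np.stack([r.observed for r in records])
    n, n_end = labels.shape

    strat_k = None
    for k in range(n_end):
        vals = labels[observed[:, k], k]
        if vals.size and len(np.unique(vals)) > 1:
            strat_k = k
            break
        logger.warning("endpoint %d has a single observed class; ignored for stratification", k)
    if strat_k is None:
        return random_split(records, train_frac, seed)

    groups = _compound_groups(records)
    rng = np.random.default_rng(seed)
    rng.shuffle(groups)

    def group_label(g):
        for i in g:
            if observed[i, strat_k]:
                return labels[i, strat_k]
        return -1.0  # unlabeled stratum

    strata: dict = {}
    for g in groups:
        strata.setdefault(group_label(g), []).append(g)

    target_total = int(np.floor(train_frac * n))
    train, test = [], []
    leftovers = []
    for lab in sorted(strata):
        gs = strata[lab]
        size = sum(len(g) for g in gs)
        target = int(np.floor(train_frac * size))
        filled = 0
        for g in gs:
            if filled < target:
                train.extend(g)
                filled += len(g)
            else:
                leftovers.append(g)
    # top up train to the global floor from the shuffled leftovers
    for g in leftovers:
        if len(train) < target_total:
            train.extend(g)
        else:
            test.extend(g)
    return SplitAssignment(train, test, "stratified", seed)


def scaffold_key(smiles: str) -> str | None:
    """Generic Bemis–Murcko scaffold SMILES (no stereo); None on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        return MurckoScaffold.MurckoScaffoldSmiles(mol=mol, includeChirality=False)
    except Exception:  # pragma: no cover - rdkit edge cases
        return None


def scaffold_split(records, train_frac: float = 0.8) -> SplitAssignment:
    """Deterministic largest-scaffold-first split; no scaffold straddles sides."""
    buckets: dict = {}
    singleton = 0
    for i, rec in enumerate(records):
        key = scaffold_key(rec.smiles)
        if key is None:
            key = f"__failed_{singleton}"
            singleton += 1
        buckets.setdefault(key, []).append(i)
    groups = sorted(buckets.values(), key=lambda g: (-len(g), min(g)))
    train, test = _fill_train(groups, len(records), train_frac)
    return SplitAssignment(train, test, "scaffold")


def dti_fold_split(records, k: int = 6, test_fold: int = 0, seed: int = 0) -> SplitAssignment:
    """Hold out one of k near-equal folds; train on the remaining k-1."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if not 0 <= test_fold < k:
        raise ValueError(f"test_fold must be in [0, {k})")
    n = len(records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    folds = [order[bounds[i]: bounds[i + 1]] for i in range(k)]
    test = folds[test_fold]
    train = np.concatenate([f for i, f in enumerate(folds) if i != test_fold])
    return SplitAssignment(train, test, "fold", seed)


def _weight_summary(w: np.ndarray) -> dict:
    q1, q2, q3 = np.percentile(w, [25, 50, 75]) if w.size else (np.nan,) * 3
    return {
        "n": int(w.size),
        "mean": float(np.mean(w)) if w.size else np.nan,
        "sd": float(np.std(w, ddof=1)) if w.size > 1 else 0.0,
        "q1": float(q1), "median": float(q2), "q3": float(q3),
    }


def split_shift_report(records, assignment: SplitAssignment) -> dict:
    """Molecular-weight distribution diagnostic for a split.

    Returns per-side weight summaries and the two-sample
    Kolmogorov–Smirnov statistic between train and test weights (0 when
    the two sides have identical weight distributions).
    """
    weights = np.array([
        Descriptors.MolWt(Chem.MolFromSmiles(r.smiles)) for r in records
    ])
    w_train = weights[assignment.train]
    w_test = weights[assignment.test]
    if w_train.size and w_test.size:
        ks = float(stats.ks_2samp(w_train, w_test).statistic)
    else:
        ks = np.nan
    return {
        "full": _weight_summary(weights),
        "train": _weight_summary(w_train),
        "test": _weight_summary(w_test),
        "ks_statistic": ks,
        "method": assignment.method,
    }
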