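"""Batch-count-proportional task sampling for multitask training.

Each benchmark dataset is one task.  Per task i the number of training
batches is ``b_i = ceil(train_i / batch_size)`` with ``train_i =
floor(0.8 n_i)`` for molecule-only tasks and ``floor(5 n_i / 6)`` for
the affinity (DTI) tasks, whose protocol holds out one of six folds.
The sampling probability is ``pi_i = b_i / sum_j b_j`` (kept in exact
rational form) and each task's global loss-balancing weight is

    beta_i = sqrt(max_j pi_j / pi_i)

so the most frequently sampled task gets beta = 1 and rarely sampled
tasks are amplified, with a square root to smooth loss spikes.

``BENCHMARK_TASKS`` records the 13 public benchmarks (entry counts,
endpoint counts, task kind) under which the reference sampling table
was computed; feeding those sizes through this module reproduces the
published percentages (MUV 29.31%, KIBA 38.77%, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil, floor, sqrt

import numpy as np

__all__ = [
    "TaskSpec", "SamplingSchedule", "BENCHMARK_TASKS",
    "compute_batch_counts", "compute_probabilities", "compute_global_weights",
    "build_schedule", "draw_task",
]


@dataclass(frozen=True)
class TaskSpec:
    """Static description of one benchmark task."""

    name: str
    kind: str  # "classification" | "regression"
    n_endpoints: int
    n_entries: int
    requires_protein: bool = False

    def __post_init__(self):
        if self.kind not in ("classification", "regression"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.n_endpoints < 1 or self.n_entries < 1:
            raise ValueError("endpoint and entry counts must be positive")


#: The 13 public benchmarks: toxicity/bioactivity and physicochemical
#: classification, physicochemical regression, and two kinase-affinity
#: regression sets (KIBA scores; Davis pKd) that carry protein inputs.
BENCHMARK_TASKS = (
    TaskSpec("ToxCast", "classification", 617, 8577),
    TaskSpec("SIDER", "classification", 27, 1427),
    TaskSpec("MUV", "classification", 17, 93087),
    TaskSpec("Tox21", "classification", 12, 7831),
    TaskSpec("ClinTox", "classification", 2, 1480),
    TaskSpec("HIV", "classification", 1, 41127),
    TaskSpec("BACE", "classification", 1, 1513),
    TaskSpec("BBBP", "classification", 1, 2039),
    TaskSpec("Lipo", "regression", 1, 4200),
    TaskSpec("Delaney", "regression", 1, 1128),
    TaskSpec("FreeSolv", "regression", 1, 642),
    TaskSpec("KIBA", "regression", 1, 118254, requires_protein=True),
    TaskSpec("Davis", "regression", 1, 30056, requires_protein=True),
)


def compute_batch_counts(dataset_size: int, is_dti_fold_task: bool, batch_size: int = 32) -> int:
    """Number of training batches for one task under the split conventions."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if dataset_size < 1:
        raise ValueError("dataset_size must be >= 1")
    if is_dti_fold_task:
        train = floor(5 * dataset_size / 6)
    else:
        train = floor(0.8 * dataset_size)
    return ceil(train / batch_size)


def compute_probabilities(batch_counts) -> list:
    """Exact rational sampling probabilities pi_i = b_i / sum(b)."""
    counts = list(batch_counts)
    if not counts:
        raise ValueError("empty task list")
    if any(c < 1 for c in counts):
        raise ValueError("all batch counts must be >= 1")
    total = sum(counts)
    return [Fraction(c, total) for c in counts]


def compute_global_weights(probabilities) -> list:
    """beta_i = sqrt(max pi / pi_i); the most-sampled task gets exactly 1."""
    probs = [Fraction(p) for p in probabilities]
    if any(p <= 0 for p in probs):
        raise ValueError("probabilities must be positive")
    top = max(probs)
    return [float(sqrt(top / p)) for p in probs]


@dataclass
class SamplingSchedule:
    """Per-task batch counts, sampling probabilities and global weights."""

    task_names: list
    train_sizes: list
    batch_counts: list
    probabilities: list  # exact Fractions summing to 1
    betas: list = field(default_factory=list)

    def __post_init__(self):
        if not self.betas:
            self.betas = compute_global_weights(self.probabilities)
        assert sum(self.probabilities) == 1

    @property
    def draws_per_epoch(self) -> int:
        return int(sum(self.batch_counts))

    def percentage(self, name: str, decimals: int = 2) -> float:
        i = self.task_names.index(name)
        return round(float(self.probabilities[i]) * 100.0, decimals)

    def beta(self, name: str) -> float:
        return self.betas[self.task_names.index(name)]

    def as_table(self) -> list:
        """Rows of (task, representation, pi %, beta) for display."""
        rows = []
        for name, p, b in zip(self.task_names, self.probabilities, self.betas):
            rows.append((name, round(float(p) * 100, 2), round(b, 2)))
        return rows


def build_schedule(tasks, batch_size: int = 32, train_sizes=None) -> SamplingSchedule:
    """Build the sampling schedule for a list of :class:`TaskSpec`.

    ``train_sizes`` overrides the convention-derived train sizes (used
    when actual split sizes are known); batch counts are always
    ``ceil(train / batch_size)``.
    """
    tasks = list(tasks)
    names = [t.name for t in tasks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate task names")
    if train_sizes is None:
        train_sizes = [
            floor(5 * t.n_entries / 6) if t.requires_protein else floor(0.8 * t.n_entries)
            for t in tasks
        ]
    counts = [ceil(ts / batch_size) for ts in train_sizes]
    probs = compute_probabilities(counts)
    return SamplingSchedule(names, list(train_sizes), counts, probs)


def draw_task(schedule: SamplingSchedule, rng: np.random.Generator) -> int:
    """Sample a task index with probability pi_i (with replacement)."""
    p = np.array([float(x) for x in schedule.probabilities])
    p /= p.sum()
    return int(rng.choice(len(p), p=p))
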