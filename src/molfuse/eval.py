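"""Per-task test metrics: ROC-AUC for classification, RMSE for regression.

Multi-endpoint classification tasks report the unweighted mean AUC over
endpoints that have both classes observed in the test set (the usual
benchmark convention); endpoints with a single observed class are
skipped and counted.  Tied scores use the midrank convention (as in
scikit-learn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["EvalReport", "roc_auc_task", "rmse_task", "evaluate_model"]


class UndefinedMetricError(ValueError):
    """No endpoint with both classes observed."""


@dataclass
class EvalReport:
    task: str
    metric: str  # "auc" | "rmse"
    value: float
    per_endpoint: list = field(default_factory=list)
    n_evaluated: int = 0
    n_endpoints_skipped: int = 0


def roc_auc_endpoints(scores, labels, observed):
    """Per-endpoint AUC over observed entries; NaN where undefined."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    observed = np.asarray(observed, dtype=bool)
    out = []
    for k in range(scores.shape[1]):
        m = observed[:, k]
        y = labels[m, k]
        if y.size == 0 or len(np.unique(y)) < 2:
            out.append(np.nan)
            continue
        out.append(float(roc_auc_score(y, scores[m, k])))
    return out


def roc_auc_task(scores, labels, observed) -> float:
    """Unweighted mean AUC over endpoints with both classes observed."""
    per = roc_auc_endpoints(scores, labels, observed)
    valid = [a for a in per if not np.isnan(a)]
    if not valid:
        raise UndefinedMetricError("no endpoint with both observed classes")
    return float(np.mean(valid))


def rmse_task(preds, targets) -> float:
    preds = np.asarray(preds, dtype=np.float64).ravel()
    targets = np.asarray(targets, dtype=np.float64).ravel()
    if preds.size == 0:
        raise ValueError("empty prediction set")
    return float(np.sqrt(np.mean((preds - targets) ** 2)))


def predict_task(model, data, batch_size: int = 64) -> np.ndarray:
    """Run the model over one task's data in evaluation mode -> (N, K)."""
    model.eval_mode()
    outs = []
    n = data.mol_ids.shape[0]
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        prot = data.prot_tokens[lo:hi] if data.prot_tokens is not None else None
        z = model.forward_task(data.spec.name, data.mol_ids[lo:hi],
                               data.mol_mask[lo:hi], prot)
        outs.append(z.data.copy())
    return np.concatenate(outs, axis=0)


def evaluate_model(model, task_data: dict, batch_size: int = 64) -> dict:
    """Evaluate every task in ``task_data`` -> {task: EvalReport}."""
    reports = {}
    for name, data in task_data.items():
        z = predict_task(model, data, batch_size)
        if data.spec.kind == "classification":
            per = roc_auc_endpoints(z, data.labels, data.observed)
            valid = [a for a in per if not np.isnan(a)]
            if not valid:
                raise UndefinedMetricError(f"task {name}: no valid endpoint")
            reports[name] = EvalReport(
                task=name, metric="auc", value=float(np.mean(valid)),
                per_endpoint=per, n_evaluated=int(data.observed.sum()),
                n_endpoints_skipped=sum(1 for a in per if np.isnan(a)))
        else:
            reports[name] = EvalReport(
                task=name, metric="rmse",
                value=rmse_task(z, data.labels),
                per_endpoint=[], n_evaluated=int(data.labels.size),
                n_endpoints_skipped=0)
    return reports
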