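"""Train the tiny fusion model on three synthetic tasks in MTL mode.

This is the package's end-to-end demonstration: a multi-endpoint
classification table with 30% missing labels, a continuous
physicochemical-style target, and ligand-protein affinities whose
proteins span two encoder segments, trained jointly with
batch-count-proportional task sampling and focal/MSE losses.

Runs a shortened schedule (15 epochs) to stay quick; the acceptance
study uses the full 50-epoch configuration.  Expect a few minutes of
CPU time; metrics improve with the full schedule.
"""

from molfuse.study import SmokeStudyConfig, run_smoke_study

cfg = SmokeStudyConfig(epochs=15, seed=0)
metrics, model, log = run_smoke_study(cfg)

print("per-epoch mean sampled-batch losses (first/last):")
for entry in (log[0], log[-1]):
    losses = ", ".join(f"{k}={v:.3f}" for k, v in sorted(entry["loss"].items()))
    print(f"  epoch {entry['epoch']:2d}: {losses}")

print("\nheld-out metrics:")
print(f"  classification mean AUC : {metrics['clf_auc']:.3f} "
      f"(per endpoint {[round(a, 3) for a in metrics['clf_auc_per_endpoint']]})")
print(f"  regression     R^2/RMSE : {metrics['reg_r2']:.3f} / {metrics['reg_rmse']:.3f}")
print(f"  affinity (DTI) R^2/RMSE : {metrics['dti_r2']:.3f} / {metrics['dti_rmse']:.3f}")
print("\nAUC near 1 and R^2 near 1 mean the planted structural rules and "
      "linear affinity signal were recovered from sequence input alone.")
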