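"""Training loop contracts: schedules, freezing, accumulation, determinism."""

import numpy as np
import pytest

from molfuse.model import EncoderConfig, build_model
from molfuse.schedule import SamplingSchedule, TaskSpec, build_schedule, compute_probabilities
from molfuse.train import (AdamW, TaskData, TrainConfig, fine_tune_heads, lr_at,
                           train_multitask, train_single_task)

TINY = dict(n_layers=2, n_heads=2, hidden=16, max_len=16, dropout=0.0)


def _toy_task(name, kind="classification", k=2, n=48, seed=0, protein=False):
    rng = np.random.default_rng(seed)
    ids = rng.integers(4, 30, size=(n, 16))
    ids[:, 0] = 1
    mask = np.ones((n, 16), dtype=np.int64)
    if kind == "classification":
        labels = rng.integers(0, 2, size=(n, k)).astype(float)
    else:
        labels = rng.normal(size=(n, k))
    observed = np.ones((n, k), dtype=bool)
    prot = [list(rng.integers(4, 30, size=10)) for _ in range(n)] if protein else None
    spec = TaskSpec(name, kind, k, n, requires_protein=protein)
    return spec, TaskData(spec=spec, mol_ids=ids, mol_mask=mask, labels=labels,
                          observed=observed, prot_tokens=prot)


def _model(specs, freeze=1, seed=0):
    mol_cfg = EncoderConfig(vocab_size=30, freeze_first_k=freeze, **TINY)
    prot_cfg = EncoderConfig(vocab_size=30, freeze_first_k=freeze, **TINY)
    return build_model(mol_cfg, prot_cfg, specs, shared_dim=16, seed=seed)


def _snapshot(model, predicate=lambda n: True):
    return {n: p.data.copy() for n, p in model.named_parameters() if predicate(n)}


class TestLRSchedule:
    def test_shape(self):
        total = 100
        scales = [lr_at(s, total, 0.10) for s in range(total + 1)]
        assert scales[0] == 0.0
        assert scales[10] == 1.0
        assert max(scales) == 1.0
        assert scales[-1] == 0.0
        diffs = np.diff(scales)
        assert np.all(diffs[:10] > 0) and np.all(diffs[10:] <= 0)


class TestConfig:
    def test_effective_batch(self):
        cfg = TrainConfig(batch_size=32, grad_accum=2)
        assert cfg.effective_batch == 64

    def test_invalid_warmup_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(warmup_frac=1.0)


class TestMultitask:
    def test_frozen_parameters_bit_identical(self):
        spec, data = _toy_task("a")
        model = _model([spec], freeze=1)
        before = _snapshot(model, lambda n: True)
        cfg = TrainConfig(batch_size=16, grad_accum=1, lr=1e-3, epochs=2, seed=0)
        train_single_task(model, data, cfg)
        for name, p in model.named_parameters():
            if not p.requires_grad:
                np.testing.assert_array_equal(p.data, before[name])
            elif name.startswith("head"):
                assert not np.array_equal(p.data, before[name])

    def test_one_hot_schedule_equals_single_task(self):
        spec, data = _toy_task("a")
        cfg = TrainConfig(batch_size=16, grad_accum=1, lr=1e-3, epochs=2, seed=3)
        m1 = _model([spec], seed=1)
        m2 = _model([spec], seed=1)
        _, log1 = train_single_task(m1, data, cfg)
        sched = SamplingSchedule([spec.name], [data.n], [3],
                                 compute_probabilities([3]))
        _, log2 = train_multitask(m2, {spec.name: data}, sched, cfg)
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_fixed_seed_bit_identical_logs(self):
        specs_data = [_toy_task("a"), _toy_task("b", kind="regression", k=1, seed=1)]
        specs = [s for s, _ in specs_data]
        data = {s.name: d for s, d in specs_data}
        cfg = TrainConfig(batch_size=16, grad_accum=2, lr=1e-3, epochs=2, seed=7)
        sched = build_schedule(specs, batch_size=16, train_sizes=[48, 48])
        _, log1 = train_multitask(_model(specs, seed=2), data, sched, cfg)
        _, log2 = train_multitask(_model(specs, seed=2), data, sched, cfg)
        assert log1 == log2

    def test_schedule_data_mismatch_rejected(self):
        spec, data = _toy_task("a")
        other = TaskSpec("b", "regression", 1, 48)
        sched = build_schedule([spec, other], batch_size=16, train_sizes=[48, 48])
        with pytest.raises(ValueError):
            train_multitask(_model([spec, other]), {"a": data}, sched,
                            TrainConfig(epochs=1))

    def test_losses_decrease_on_learnable_tasks(self):
        # planted linear signal in random tokens: token 7 count drives label
        rng = np.random.default_rng(0)
        n = 96
        ids = rng.integers(4, 30, size=(n, 16))
        ids[:, 0] = 1
        labels = (np.sum(ids == 7, axis=1) > 1).astype(float)[:, None]
        spec = TaskSpec("sig", "classification", 1, n)
        data = TaskData(spec=spec, mol_ids=ids,
                        mol_mask=np.ones((n, 16), dtype=np.int64),
                        labels=labels, observed=np.ones((n, 1), dtype=bool))
        model = _model([spec], freeze=0)
        cfg = TrainConfig(batch_size=16, grad_accum=1, lr=3e-3, epochs=6, seed=0)
        _, log = train_multitask(model, {"sig": data},
                                 build_schedule([spec], batch_size=16, train_sizes=[n]),
                                 cfg)
        losses = [e["loss"]["sig"] for e in log]
        drops = sum(b < a for a, b in zip(losses, losses[1:]))
        assert drops >= len(losses) - 2
        assert losses[-1] < losses[0]


class TestGradAccumEquivalence:
    def test_two_half_batches_equal_one_full_batch(self):
        # dropout off; compare accumulated gradients directly
        spec, data = _toy_task("a", n=32)
        model = _model([spec], freeze=0)
        model.eval_mode()  # no dropout
        from molfuse.train import _task_loss_graph
        import molfuse._autodiff as ad
        from molfuse._autodiff import Tensor

        full = _task_loss_graph(model, data, np.arange(32), beta=1.0)
        full.backward()
        g_full = {n: p.grad.copy() for n, p in model.named_parameters()
                  if p.requires_grad and p.grad is not None}
        for _, p in model.named_parameters():
            p.grad = None
        for half in (np.arange(16), np.arange(16, 32)):
            loss = ad.mul(_task_loss_graph(model, data, half, beta=1.0),
                          Tensor(np.float32(0.5)))
            loss.backward()
        for n, p in model.named_parameters():
            if n in g_full:
                np.testing.assert_allclose(p.grad, g_full[n], atol=5e-6)


class TestSingleTask:
    def test_beta_forced_to_one(self):
        spec, data = _toy_task("solo")
        model = _model([spec])
        _, log = train_single_task(model, data, TrainConfig(batch_size=16, epochs=1))
        assert log  # ran; beta assertion is inside train_single_task


class TestFineTuneHeads:
    def test_only_new_heads_move(self):
        spec, data = _toy_task("base")
        model = _model([spec])
        new_spec, new_data = _toy_task("extra", kind="regression", k=1, seed=5)
        before = _snapshot(model)
        cfg = TrainConfig(batch_size=16, grad_accum=1, lr=1e-3, epochs=2, seed=0)
        model, _ = fine_tune_heads(model, {"extra": new_data}, cfg)
        moved = {n for n, p in model.named_parameters()
                 if n in before and not np.array_equal(p.data, before[n])}
        assert moved == set()  # every pre-existing parameter untouched
        assert any(n.startswith("head.extra") for n, _ in model.named_parameters())

    def test_name_collision_rejected(self):
        spec, data = _toy_task("base")
        model = _model([spec])
        with pytest.raises(ValueError):
            fine_tune_heads(model, {"base": data}, TrainConfig(epochs=1))

    def test_new_head_learns_linear_signal(self):
        spec, data = _toy_task("base")
        model = _model([spec], freeze=0)
        cfg = TrainConfig(batch_size=16, grad_accum=1, lr=1e-2, epochs=1, seed=0)
        train_single_task(model, data, cfg)
        # new task whose labels are a linear readout of the (frozen) fused
        # representation: learnable by a head alone
        rng = np.random.default_rng(9)
        n = 64
        ids = rng.integers(4, 30, size=(n, 16))
        ids[:, 0] = 1
        mask = np.ones((n, 16), dtype=np.int64)
        model.eval_mode()
        fused = model.fuse(model.encode_molecule(ids, mask)).data
        w = rng.normal(size=fused.shape[1])
        y = (fused @ w > np.median(fused @ w)).astype(float)[:, None]
        new_spec = TaskSpec("readout", "classification", 1, n)
        new_data = TaskData(spec=new_spec, mol_ids=ids, mol_mask=mask, labels=y,
                            observed=np.ones((n, 1), dtype=bool))
        cfg = TrainConfig(batch_size=16, grad_accum=1, lr=1e-2, epochs=20, seed=0)
        model, _ = fine_tune_heads(model, {"readout": new_data}, cfg)
        from molfuse.eval import predict_task, roc_auc_task
        z = predict_task(model, new_data)
        assert roc_auc_task(z, y, new_data.observed) > 0.75


class TestAdamW:
    def test_frozen_and_gradless_params_untouched(self):
        import molfuse._autodiff as ad
        a = ad.Tensor(np.ones(3), requires_grad=True)
        b = ad.Tensor(np.ones(3), requires_grad=False)
        a.grad = np.ones(3)
        b.grad = np.ones(3)
        opt = AdamW([("a", a), ("b", b)], lr=0.1)
        opt.step()
        assert not np.array_equal(a.data, np.ones(3))
        np.testing.assert_array_equal(b.data, np.ones(3))
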