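"""Fusion model contracts: shapes, zero placeholders, freezing, routing."""

import numpy as np
import pytest

import molfuse._autodiff as ad
from molfuse.model import EncoderConfig, FusionModel, ModelTask, build_model, set_freezing
from molfuse.schedule import TaskSpec

TINY = dict(n_layers=2, n_heads=2, hidden=32, max_len=24, dropout=0.1, freeze_first_k=1)


@pytest.fixture()
def tiny_model():
    mol_cfg = EncoderConfig(vocab_size=50, **TINY)
    prot_cfg = EncoderConfig(vocab_size=60, **TINY)
    tasks = [ModelTask("tox", "classification", 3),
             ModelTask("sol", "regression", 1),
             ModelTask("aff", "regression", 1, requires_protein=True)]
    return build_model(mol_cfg, prot_cfg, tasks, shared_dim=16, seed=0)


def _batch(rng, n=4, t=24, vocab=50, real=18):
    ids = rng.integers(4, vocab, size=(n, t))
    mask = np.zeros((n, t), dtype=np.int64)
    mask[:, :real] = 1
    ids[:, real:] = 0
    ids[:, 0] = 1
    return ids, mask


class TestConfig:
    def test_hidden_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            EncoderConfig(vocab_size=10, hidden=30, n_heads=4)

    def test_freeze_bounds_enforced(self):
        with pytest.raises(ValueError):
            EncoderConfig(vocab_size=10, n_layers=2, freeze_first_k=3,
                          n_heads=2, hidden=16)

    def test_defaults_match_reference_architecture(self):
        cfg = EncoderConfig(vocab_size=100)
        assert (cfg.n_layers, cfg.n_heads, cfg.hidden, cfg.max_len,
                cfg.freeze_first_k, cfg.dropout) == (6, 12, 768, 512, 4, 0.1)


class TestBuild:
    def test_head_width_is_total_endpoints(self, tiny_model):
        assert tiny_model.head_output_width() == 5

    def test_benchmark_registry_width(self):
        # 13 benchmark tasks at a tiny hidden size: total head width 683
        from molfuse.schedule import BENCHMARK_TASKS
        mol_cfg = EncoderConfig(vocab_size=50, **TINY)
        prot_cfg = EncoderConfig(vocab_size=60, **TINY)
        model = build_model(mol_cfg, prot_cfg, BENCHMARK_TASKS, shared_dim=16)
        assert model.head_output_width() == 683

    def test_duplicate_task_names_rejected(self):
        mol_cfg = EncoderConfig(vocab_size=50, **TINY)
        tasks = [ModelTask("a", "regression", 1)] * 2
        with pytest.raises(ValueError):
            FusionModel(mol_cfg, mol_cfg, tasks)

    def test_full_freeze_leaves_no_trainable_encoder_params(self):
        cfg = EncoderConfig(vocab_size=50, n_layers=2, n_heads=2, hidden=32,
                            max_len=24, freeze_first_k=2)
        model = build_model(cfg, cfg, [ModelTask("t", "regression", 1)])
        enc_names = {n for n, _ in model.mol_encoder.params("mol")
                     if "final_ln" not in n}
        trainable = {n for n, p in model.named_parameters() if p.requires_grad}
        assert not (enc_names & trainable)


class TestEncodeMolecule:
    def test_eval_mode_deterministic(self, tiny_model, rng):
        ids, mask = _batch(rng)
        tiny_model.eval_mode()
        a = tiny_model.encode_molecule(ids, mask).data
        b = tiny_model.encode_molecule(ids, mask).data
        np.testing.assert_array_equal(a, b)

    def test_batch_equivariance(self, tiny_model, rng):
        ids, mask = _batch(rng)
        tiny_model.eval_mode()
        out = tiny_model.encode_molecule(ids, mask).data
        perm = rng.permutation(ids.shape[0])
        out_p = tiny_model.encode_molecule(ids[perm], mask[perm]).data
        np.testing.assert_allclose(out_p, out[perm], rtol=1e-5)

    def test_padding_extension_invariance(self, rng):
        cfg = EncoderConfig(vocab_size=50, n_layers=2, n_heads=2, hidden=32,
                            max_len=32, dropout=0.0, freeze_first_k=0)
        model = FusionModel(cfg, cfg, [ModelTask("t", "regression", 1)], seed=0)
        model.eval_mode()
        ids, mask = _batch(rng, t=24, real=10)
        short = model.encode_molecule(ids, mask).data
        pad = np.zeros((4, 8), dtype=np.int64)
        longer = model.encode_molecule(np.concatenate([ids, pad], axis=1),
                                       np.concatenate([mask, pad], axis=1)).data
        np.testing.assert_allclose(longer, short, atol=1e-5)


class TestProteinSegments:
    def test_two_full_segments_distinct(self, tiny_model, rng):
        cap = tiny_model.prot_cfg.max_len - 2
        toks = [list(rng.integers(4, 60, size=2 * cap)) for _ in range(3)]
        tiny_model.eval_mode()
        c1, c2 = tiny_model.encode_protein_two_segments(toks)
        assert c1.shape == c2.shape == (3, 32)
        assert not np.allclose(c1.data, c2.data)

    def test_empty_second_segment_is_zero(self, tiny_model, rng):
        cap = tiny_model.prot_cfg.max_len - 2
        toks = [list(rng.integers(4, 60, size=cap // 2))]
        tiny_model.eval_mode()
        c1, c2 = tiny_model.encode_protein_two_segments(toks)
        assert np.all(c2.data == 0)
        assert np.any(c1.data != 0)

    def test_overlong_stream_truncated(self, tiny_model, rng):
        cap = tiny_model.prot_cfg.max_len - 2
        toks = [list(rng.integers(4, 60, size=3 * cap))]
        tiny_model.eval_mode()
        c1a, c2a = tiny_model.encode_protein_two_segments(toks)
        c1b, c2b = tiny_model.encode_protein_two_segments([toks[0][: 2 * cap]])
        np.testing.assert_allclose(c1a.data, c1b.data)
        np.testing.assert_allclose(c2a.data, c2b.data)

    def test_segments_share_weights(self, tiny_model, rng):
        cap = tiny_model.prot_cfg.max_len - 2
        toks = [list(rng.integers(4, 60, size=2 * cap))]
        tiny_model.eval_mode()
        c1, c2 = tiny_model.encode_protein_two_segments(toks)
        w = tiny_model.prot_encoder.layers[0].wv.W
        w.data = w.data + rng.normal(0, 0.1, size=w.data.shape).astype(w.data.dtype)
        d1, d2 = tiny_model.encode_protein_two_segments(toks)
        assert not np.allclose(c1.data, d1.data)
        assert not np.allclose(c2.data, d2.data)


class TestFuse:
    def test_molecule_only_zero_blocks(self, tiny_model, rng):
        ids, mask = _batch(rng)
        tiny_model.eval_mode()
        cls = tiny_model.encode_molecule(ids, mask)
        fused = tiny_model.fuse(cls)
        assert fused.shape == (4, 96)  # 3 * 32
        assert np.all(fused.data[:, 32:] == 0)
        assert np.any(fused.data[:, :32] != 0)

    def test_default_hidden_gives_2304(self):
        cfg = EncoderConfig(vocab_size=50, n_layers=1, n_heads=12, hidden=768,
                            max_len=16, freeze_first_k=0)
        model = FusionModel(cfg, cfg, [ModelTask("t", "regression", 1)], seed=0)
        model.eval_mode()
        ids = np.ones((2, 16), dtype=np.int64)
        mask = np.ones((2, 16), dtype=np.int64)
        fused = model.fuse(model.encode_molecule(ids, mask))
        assert fused.shape[-1] == 2304

    def test_dti_protein_blocks_nonzero(self, tiny_model, rng):
        ids, mask = _batch(rng)
        toks = [list(rng.integers(4, 60, size=10)) for _ in range(4)]
        tiny_model.eval_mode()
        fused = tiny_model.fuse(tiny_model.encode_molecule(ids, mask),
                                tiny_model.encode_protein_two_segments(toks))
        assert np.any(fused.data[:, 32:64] != 0)


class TestForwardTask:
    def test_molecule_loss_gives_zero_protein_gradient(self, tiny_model, rng):
        ids, mask = _batch(rng)
        tiny_model.eval_mode()
        z = tiny_model.forward_task("tox", ids, mask)
        loss = ad.mean_(ad.mul(z, z))
        loss.backward()
        for name, p in tiny_model.prot_encoder.params("prot"):
            assert p.grad is None or np.all(p.grad == 0), name

    def test_heads_differ_on_same_input(self, tiny_model, rng):
        ids, mask = _batch(rng)
        tiny_model.eval_mode()
        z_tox = tiny_model.forward_task("tox", ids, mask)
        z_sol = tiny_model.forward_task("sol", ids, mask)
        assert z_tox.shape == (4, 3)
        assert z_sol.shape == (4, 1)
        assert not np.allclose(z_tox.data[:, :1], z_sol.data)

    def test_protein_task_without_protein_rejected(self, tiny_model, rng):
        ids, mask = _batch(rng)
        with pytest.raises(ValueError):
            tiny_model.forward_task("aff", ids, mask)

    def test_unknown_task_rejected(self, tiny_model, rng):
        ids, mask = _batch(rng)
        with pytest.raises(KeyError):
            tiny_model.forward_task("nope", ids, mask)


class TestFreezing:
    def test_head_tune_freezes_encoders_and_shared(self, tiny_model):
        set_freezing(tiny_model, "head_tune")
        for name, p in tiny_model.named_parameters():
            if name.startswith(("mol", "prot", "shared")):
                assert not p.requires_grad, name
            else:
                assert p.requires_grad, name

    def test_mtl_freezes_embeddings_and_lower_layers(self, tiny_model):
        set_freezing(tiny_model, "mtl")  # freeze_first_k = 1 of 2
        frozen = {n for n, p in tiny_model.named_parameters() if not p.requires_grad}
        assert "mol.tok_emb" in frozen and "mol.pos_emb" in frozen
        assert any(n.startswith("mol.layers.0") for n in frozen)
        assert not any(n.startswith("mol.layers.1") for n in frozen)

    def test_invalid_mode_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            set_freezing(tiny_model, "all")


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model, tmp_path, rng):
        ids, mask = _batch(rng)
        tiny_model.eval_mode()
        before = tiny_model.forward_task("tox", ids, mask).data
        tiny_model.save(str(tmp_path / "ckpt"))
        loaded = FusionModel.load(str(tmp_path / "ckpt"))
        loaded.eval_mode()
        after = loaded.forward_task("tox", ids, mask).data
        np.testing.assert_array_equal(before, after)

    def test_add_task_collision_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.add_task(TaskSpec("tox", "classification", 3, 10))
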