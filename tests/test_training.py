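import numpy as np
import pytest

from clinvla.adapters import reversible_forward
from clinvla.autograd import Tensor
from clinvla.config import ModelConfig, TrainConfig
from clinvla.models import build_model, _reversible_apply
from clinvla.training import (
    AdamW,
    contrastive_objective,
    embed_dataset,
    make_optimizer,
    paper_objective,
    partition_parameters,
    preprocess_record,
    train_loop,
)


def toy_config():
    # 2 layers, h=8, d=2, small image/vocab: hand-countable
    return ModelConfig(h=8, depth=2, n_heads=2, d=2, ffn_mult=2,
                       vocab_size=64, image_side=32, patch_side=16,
                       max_text_len=128, n_locals=2, seed=0)


def hand_census(cfg: ModelConfig):
    """Independent parameter count for the toy model (with biases)."""
    h, d = cfg.h, cfg.d
    lang = (h * d + d) + (d * h + h)
    task = lang
    ln = 2 * h
    per_block_trainable = lang + task + ln
    half, quarter = h // 2, h // 4
    rev = 2 * ((half * quarter + quarter) + (quarter * half + half))
    n_blocks = 2 * cfg.depth  # two encoders
    trainable_pretrain = n_blocks * per_block_trainable + 2 * rev
    trainable_downstream = n_blocks * (task + ln)

    f = cfg.ffn_mult * h
    per_block_frozen = 4 * h * h + (h * f + f) + (f * h + h) + 2 * h
    frozen = (n_blocks * per_block_frozen
              + cfg.patch_dim * h + cfg.n_patches * h      # image embed+pos
              + cfg.vocab_size * h + cfg.max_text_len * h)  # text embed+pos
    total_pre = trainable_pretrain + frozen
    return trainable_pretrain, trainable_downstream, total_pre


class TestPartition:
    def test_pretrain_census_matches_hand_count(self):
        cfg = toy_config()
        part = partition_parameters(build_model(cfg), "pretrain")
        expected_trainable, _, expected_total = hand_census(cfg)
        assert part.counts["trainable"] == expected_trainable
        assert part.counts["total"] == expected_total
        assert part.counts["fraction"] == pytest.approx(
            expected_trainable / expected_total)

    def test_downstream_census(self):
        cfg = toy_config()
        part = partition_parameters(build_model(cfg), "downstream")
        _, expected_downstream, _ = hand_census(cfg)
        assert part.counts["trainable"] == expected_downstream
        assert all(".task_adapter." in k or ".adapter_ln." in k
                   for k in part.trainable)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            partition_parameters(build_model(toy_config()), "finetune")

    def test_empty_trainable_rejected(self):
        class Husk:
            def trainable_tensors(self):
                return {}

            def backbone_arrays(self):
                return {"w": np.zeros(3)}

        with pytest.raises(ValueError, match="no trainable"):
            partition_parameters(Husk(), "pretrain")

    def test_fraction_monotone_in_d(self):
        fracs = []
        for d in (2, 4):
            cfg = ModelConfig(h=16, depth=1, n_heads=2, d=d, vocab_size=64,
                              image_side=32, seed=0)
            fracs.append(
                partition_parameters(build_model(cfg), "pretrain")
                .counts["fraction"])
        assert fracs[1] > fracs[0]


class TestAdamW:
    def test_per_group_learning_rates(self):
        # 1-parameter probe per group: first-step displacement ~ lr
        pa = Tensor(np.array([0.0]), requires_grad=True)
        pb = Tensor(np.array([0.0]), requires_grad=True)
        opt = AdamW([{"params": {"a": pa}, "lr": 1e-4},
                     {"params": {"b": pb}, "lr": 5e-5}], weight_decay=0.0)
        pa.grad = np.array([3.0])
        pb.grad = np.array([3.0])
        opt.step()
        assert abs(pa.data[0]) == pytest.approx(1e-4, rel=1e-6)
        assert abs(pb.data[0]) == pytest.approx(5e-5, rel=1e-6)

    def test_zero_lr_is_identity(self):
        p = Tensor(np.array([1.5]), requires_grad=True)
        opt = AdamW([{"params": {"p": p}, "lr": 0.0}], weight_decay=1e-4)
        p.grad = np.array([2.0])
        before = p.data.copy()
        opt.step()
        np.testing.assert_array_equal(p.data, before)


class TestModelGraphConsistency:
    def test_graph_reversible_matches_functional(self, tiny_model, rng):
        enc = tiny_model.image_encoder
        x = rng.normal(size=(2, 3, tiny_model.cfg.h))
        graph = _reversible_apply(Tensor(x), enc.t_rev, tiny_model.cfg.h)
        np.testing.assert_allclose(graph.data,
                                   reversible_forward(x, enc.rev), atol=1e-12)

    def test_fresh_adapters_start_neutral(self, tiny_model, rng):
        # zeroed up-projections: the embedding-level coupling is identity
        x = rng.normal(size=(4, tiny_model.cfg.h))
        np.testing.assert_array_equal(
            reversible_forward(x, tiny_model.image_encoder.rev), x)

    def test_build_deterministic(self):
        cfg = toy_config()
        a, b = build_model(cfg), build_model(cfg)
        for k, arr in a.backbone_arrays().items():
            np.testing.assert_array_equal(arr, b.backbone_arrays()[k])


class TestObjectives:
    def _batch(self, tiny_dataset, tiny_model, n=6):
        from clinvla.text_pipeline import HashTokenizer
        from clinvla.training import _batch_arrays

        records, _, _ = tiny_dataset
        tok = HashTokenizer(vocab_size=tiny_model.cfg.vocab_size)
        items = [preprocess_record(r, tiny_model.cfg, tok, 0)
                 for r in records[:n]]
        return _batch_arrays(tiny_model, items)

    def test_paper_objective_matches_numpy_losses(self, tiny_dataset,
                                                  tiny_model):
        from clinvla.alignment import (
            global_alignment_loss,
            local_alignment_loss,
        )
        from clinvla.models import ClinVLAModel

        img_raw, txt_raw, txt_keep = self._batch(tiny_dataset, tiny_model)
        img_tok = tiny_model.encode_image_batch(img_raw)
        txt_tok = tiny_model.encode_text_batch(txt_raw)
        n_loc = tiny_model.cfg.n_locals
        loss, g_term, l_term = paper_objective(img_tok, txt_tok, txt_keep,
                                               0.8, n_loc)
        # independent recomputation with the plain-NumPy loss functions
        img_g = img_tok.data.mean(axis=1)
        w = txt_keep[:, :, None].astype(float)
        txt_g = (txt_tok.data * w).sum(axis=1) / w.sum(axis=1)
        exp_g = np.mean([global_alignment_loss(a, b)
                         for a, b in zip(img_g, txt_g)])
        bounds_i = np.linspace(0, img_tok.shape[1], n_loc + 1).astype(int)
        bounds_t = np.linspace(0, txt_tok.shape[1], n_loc + 1).astype(int)
        exp_l = np.mean([
            local_alignment_loss(
                np.stack([img_tok.data[b, lo:hi].mean(axis=0)
                          for lo, hi in zip(bounds_i[:-1], bounds_i[1:])]),
                np.stack([txt_tok.data[b, lo:hi].mean(axis=0)
                          for lo, hi in zip(bounds_t[:-1], bounds_t[1:])]))
            for b in range(img_g.shape[0])
        ])
        assert float(g_term.data) == pytest.approx(exp_g, abs=1e-10)
        assert float(l_term.data) == pytest.approx(exp_l, abs=1e-10)
        assert float(loss.data) == pytest.approx(exp_g + 0.8 * exp_l, abs=1e-10)

    def test_contrastive_matches_numpy(self, tiny_dataset, tiny_model):
        from clinvla.alignment import batch_contrastive_loss
        from clinvla.models import ClinVLAModel

        img_raw, txt_raw, txt_keep = self._batch(tiny_dataset, tiny_model)
        img_tok = tiny_model.encode_image_batch(img_raw)
        txt_tok = tiny_model.encode_text_batch(txt_raw)
        loss = contrastive_objective(img_tok, txt_tok, txt_keep, 0.1)
        img_g = img_tok.data.mean(axis=1)
        w = txt_keep[:, :, None].astype(float)
        txt_g = (txt_tok.data * w).sum(axis=1) / w.sum(axis=1)
        assert float(loss.data) == pytest.approx(
            batch_contrastive_loss(img_g, txt_g, 0.1), abs=1e-10)


class TestTrainLoop:
    def small_records(self, tiny_dataset, n=8):
        records, _, _ = tiny_dataset
        return list(records[:n])

    def test_lr_zero_parameters_bit_identical(self, tiny_dataset, tiny_model):
        config = TrainConfig(batch_size=4, epochs=1, seed=0,
                             lr_language_adapter=0.0, lr_task_adapter=0.0,
                             lr_reversible_adapter=0.0, weight_decay=1e-4)
        before = {k: t.data.copy()
                  for k, t in tiny_model.trainable_tensors().items()}
        train_loop(self.small_records(tiny_dataset), tiny_model, config)
        for k, t in tiny_model.trainable_tensors().items():
            np.testing.assert_array_equal(t.data, before[k])

    def test_frozen_backbone_conserved(self, tiny_dataset, tiny_model):
        config = TrainConfig(batch_size=4, epochs=2, seed=0,
                             lr_task_adapter=1e-2)
        before = {k: a.copy()
                  for k, a in tiny_model.backbone_arrays().items()}
        train_loop(self.small_records(tiny_dataset), tiny_model, config)
        for k, a in tiny_model.backbone_arrays().items():
            np.testing.assert_array_equal(a, before[k])

    def test_downstream_freezes_non_task_params(self, tiny_dataset,
                                                tiny_model):
        config = TrainConfig(batch_size=4, epochs=10, max_steps=10, seed=0,
                             mode="downstream", lr_task_adapter=1e-2)
        tensors = tiny_model.trainable_tensors()
        before = {k: t.data.copy() for k, t in tensors.items()}
        train_loop(self.small_records(tiny_dataset), tiny_model, config)
        changed_task = frozen_ok = True
        for k, t in tensors.items():
            if ".task_adapter." in k or ".adapter_ln." in k:
                continue
            frozen_ok &= np.array_equal(t.data, before[k])
        task_deltas = [np.abs(t.data - before[k]).max()
                       for k, t in tensors.items() if ".task_adapter." in k]
        assert frozen_ok, "language/reversible params moved in downstream mode"
        assert max(task_deltas) > 0, "task adapters did not train"

    def test_same_seed_identical_trajectories(self, tiny_dataset):
        cfg = ModelConfig(h=16, depth=1, n_heads=2, d=4, vocab_size=128,
                          image_side=64, seed=5)
        config = TrainConfig(batch_size=4, epochs=1, max_steps=3, seed=9,
                             lr_task_adapter=1e-3)
        losses = []
        for _ in range(2):
            model = build_model(cfg)
            res = train_loop(self.small_records(tiny_dataset), model, config)
            losses.append([m["loss"] for m in res.metrics])
        assert losses[0] == losses[1]

    def test_loss_decreases_contrastive(self, tiny_dataset):
        records, _, _ = tiny_dataset
        cfg = ModelConfig(h=32, depth=2, n_heads=2, d=8, vocab_size=512,
                          image_side=64, seed=1)
        model = build_model(cfg)
        config = TrainConfig(batch_size=16, objective="contrastive", seed=1,
                             epochs=20, max_steps=50,
                             lr_task_adapter=1e-2, lr_language_adapter=5e-3,
                             lr_reversible_adapter=1e-2)
        res = train_loop(records, model, config)
        first = np.mean([m["loss"] for m in res.metrics[:5]])
        last = np.mean([m["loss"] for m in res.metrics[-5:]])
        assert last < first

    def test_divergence_aborts(self, tiny_dataset, tiny_model):
        # poison one adapter weight: the loss goes non-finite and the loop
        # must abort with a diagnostic instead of continuing
        tensors = tiny_model.trainable_tensors()
        gain = next(t for k, t in tensors.items() if k.endswith("adapter_ln.gain"))
        gain.data.flat[0] = np.nan
        config = TrainConfig(batch_size=4, seed=0, epochs=1)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_loop(self.small_records(tiny_dataset), tiny_model, config)

    def test_empty_dataset_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            train_loop([], tiny_model, TrainConfig())

    def test_checkpoint_contains_only_trainable(self, tiny_dataset,
                                                tiny_model, tmp_path):
        from clinvla.adapters import load_adapter_archive

        config = TrainConfig(batch_size=4, epochs=1, max_steps=2, seed=0)
        path = tmp_path / "ckpt.zip"
        res = train_loop(self.small_records(tiny_dataset), tiny_model,
                         config, checkpoint_path=path,
                         metrics_path=tmp_path / "m.jsonl")
        arrays, manifest = load_adapter_archive(path)
        assert set(arrays) == set(res.partition.trainable)
        assert (tmp_path / "m.jsonl").read_text().count("\n") == res.steps


class TestEmbedDataset:
    def test_shapes_and_determinism(self, tiny_dataset, tiny_model):
        records, _, _ = tiny_dataset
        img, txt = embed_dataset(records[:6], tiny_model, base_seed=0)
        img2, _ = embed_dataset(records[:6], tiny_model, base_seed=0)
        assert img.shape == (6, tiny_model.cfg.h)
        assert txt.shape == (6, tiny_model.cfg.h)
        np.testing.assert_array_equal(img, img2)
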