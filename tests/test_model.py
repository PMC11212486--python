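"""Classifier construction, training loop, prediction and persistence."""

import numpy as np
import pytest

from cppmine import nn
from cppmine.data_io import LabeledDataset, Peptide
from cppmine.hard_sampler import SamplerConfig
from cppmine.model import (CPPClassifier, ModelConfig, TrainConfig,
                           TrainedModel, VariantSpec, export_embeddings, fit,
                           init_model, predict_scores, train_epoch)
from cppmine.synthetic import SyntheticSpec, generate


@pytest.fixture
def tiny_dataset():
    return generate(SyntheticSpec(n_pos=10, ratio=5, seed=4,
                                  length_range=(5, 15)))


def tiny_fit(dataset, tiny_model_cfg, mock_embedder, mode="hard", epochs=3,
             seed=0, **kw):
    variant = (VariantSpec.full() if mode == "hard" else VariantSpec.base())
    return fit(dataset, variant, model_cfg=tiny_model_cfg,
               train_cfg=TrainConfig(batch_positives=5, epochs=epochs,
                                     seed=seed),
               sampler_cfg=SamplerConfig(K=3, M=2, seed=seed, mode=mode),
               embedder=mock_embedder, **kw)


class TestVariants:
    def test_named_variants_cover_the_ablation(self):
        assert VariantSpec.named("full").sampling == "hard"
        assert VariantSpec.named("base").sampling == "uniform"
        assert VariantSpec.named("no-esm") == VariantSpec(use_fp=True,
                                                          use_esm=False,
                                                          sampling="hard")
        assert VariantSpec.named("no-esm-fp").n_branches == 1
        with pytest.raises(ValueError):
            VariantSpec.named("nope")

    def test_mlp_input_widths(self):
        full = CPPClassifier(VariantSpec.full(), ModelConfig(), seed=0)
        assert full.input_width == 1536
        solo = CPPClassifier(VariantSpec.no_esm_fp(), ModelConfig(), seed=0)
        assert solo.input_width == 512

    def test_same_seed_identical_parameters(self, tiny_model_cfg):
        a = CPPClassifier(VariantSpec.full(), tiny_model_cfg, seed=3)
        b = CPPClassifier(VariantSpec.full(), tiny_model_cfg, seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestForward:
    def test_probabilities_valid_and_deterministic(self, tiny_dataset,
                                                   tiny_model_cfg,
                                                   mock_embedder):
        model = init_model(VariantSpec.full(), 0, tiny_model_cfg,
                           mock_embedder)
        model.store.add_peptides(tiny_dataset.peptides)
        batch = model.store.batch(tiny_dataset.ids[:6])
        p = model.classifier.forward(batch)
        assert ((0 <= p) & (p <= 1)).all()
        np.testing.assert_array_equal(p, model.classifier.forward(batch))

    def test_class_probabilities_sum_to_one(self, tiny_dataset,
                                            tiny_model_cfg, mock_embedder):
        model = init_model(VariantSpec.full(), 0, tiny_model_cfg,
                           mock_embedder)
        model.store.add_peptides(tiny_dataset.peptides)
        batch = model.store.batch(tiny_dataset.ids[:4])
        with nn.no_grad():
            probs = nn.softmax(model.classifier.logits(batch), axis=-1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_variant_branch_mismatch_raises(self, tiny_dataset,
                                            tiny_model_cfg, mock_embedder):
        model = init_model(VariantSpec.full(), 0, tiny_model_cfg,
                           mock_embedder)
        model.store.add_peptides(tiny_dataset.peptides)
        batch = model.store.batch(tiny_dataset.ids[:2])
        del batch["fp_bits"]
        with pytest.raises(ValueError, match="fingerprint"):
            model.classifier.logits(batch)


class TestTraining:
    def test_repeated_batch_loss_decreases(self, tiny_dataset, tiny_model_cfg,
                                           mock_embedder):
        """Sanity optimisation run: 20 Adam steps on one fixed batch."""
        model = init_model(VariantSpec.full(), 0, tiny_model_cfg,
                           mock_embedder)
        model.store.add_peptides(tiny_dataset.peptides)
        ids = tiny_dataset.ids[:8]
        labels = np.array(tiny_dataset.labels[:8])
        opt = nn.Adam(model.classifier.parameters(), lr=1e-2)
        losses = []
        for _ in range(20):
            loss = nn.cross_entropy(
                model.classifier.logits(model.store.batch(ids)), labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])

    def test_epoch_count_batches(self, tiny_model_cfg, mock_embedder):
        ds = generate(SyntheticSpec(n_pos=10, ratio=3, seed=1,
                                    length_range=(5, 15)))
        model = init_model(VariantSpec.full(), 0, tiny_model_cfg,
                           mock_embedder)
        model.train_cfg = TrainConfig(batch_positives=5, epochs=1, seed=0)
        model.sampler_cfg = SamplerConfig(K=2, M=2, seed=0, mode="hard")
        opt = nn.Adam(model.classifier.parameters())
        record = train_epoch(model, ds, opt, epoch=0)
        assert record["n_batches"] == 2

    def test_uniform_mode_never_scores(self, tiny_dataset, tiny_model_cfg,
                                       mock_embedder, monkeypatch):
        import cppmine.model as model_mod
        def boom(*a, **k):
            raise AssertionError("scoring invoked in uniform mode")
        monkeypatch.setattr(model_mod, "_score_ids", boom)
        model = init_model(VariantSpec.base(), 0, tiny_model_cfg,
                           mock_embedder)
        model.train_cfg = TrainConfig(batch_positives=5, epochs=1, seed=0)
        model.sampler_cfg = SamplerConfig(K=3, M=2, seed=0, mode="uniform")
        opt = nn.Adam(model.classifier.parameters())
        train_epoch(model, tiny_dataset, opt, epoch=0)  # must not raise

    def test_no_positives_raises(self, tiny_model_cfg, mock_embedder):
        ds = LabeledDataset(peptides=[Peptide("n0", "GGGG")], labels=[0])
        model = init_model(VariantSpec.full(), 0, tiny_model_cfg,
                           mock_embedder)
        with pytest.raises(ValueError, match="no positives"):
            train_epoch(model, ds, nn.Adam(model.classifier.parameters()), 0)

    def test_zero_epochs_returns_initial_state(self, tiny_dataset,
                                               tiny_model_cfg, mock_embedder):
        trained = tiny_fit(tiny_dataset, tiny_model_cfg, mock_embedder,
                           epochs=0)
        fresh = init_model(VariantSpec.full(), 0, tiny_model_cfg,
                           mock_embedder)
        for a, b in zip(trained.classifier.parameters(),
                        fresh.classifier.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_fixed_seed_identical_loss_trace(self, tiny_dataset,
                                             tiny_model_cfg, mock_embedder):
        a = tiny_fit(tiny_dataset, tiny_model_cfg, mock_embedder, seed=5)
        b = tiny_fit(tiny_dataset, tiny_model_cfg, mock_embedder, seed=5)
        assert [r["mean_loss"] for r in a.train_log] == \
               [r["mean_loss"] for r in b.train_log]

    def test_early_stopping_restores_best(self, tiny_dataset, tiny_model_cfg,
                                          mock_embedder):
        val = generate(SyntheticSpec(n_pos=5, ratio=3, seed=9,
                                     length_range=(5, 15)))
        model = fit(tiny_dataset, VariantSpec.full(),
                    model_cfg=tiny_model_cfg,
                    train_cfg=TrainConfig(batch_positives=5, epochs=4,
                                          patience=2, seed=0),
                    sampler_cfg=SamplerConfig(K=2, M=2, seed=0, mode="hard"),
                    embedder=mock_embedder, validation=val)
        assert all("val_loss" in r for r in model.train_log)


class TestPrediction:
    def test_scores_complete_and_order_invariant(self, tiny_dataset,
                                                 tiny_model_cfg,
                                                 mock_embedder):
        model = tiny_fit(tiny_dataset, tiny_model_cfg, mock_embedder, epochs=1)
        fwd = predict_scores(model, tiny_dataset)
        assert set(fwd) == set(tiny_dataset.ids)
        shuffled = tiny_dataset.subset(
            list(np.random.default_rng(0).permutation(len(tiny_dataset))))
        back = predict_scores(model, shuffled)
        for pid in fwd:
            assert fwd[pid] == pytest.approx(back[pid], abs=1e-12)

    def test_batch_size_independence(self, tiny_dataset, tiny_model_cfg,
                                     mock_embedder):
        model = tiny_fit(tiny_dataset, tiny_model_cfg, mock_embedder, epochs=1)
        s1 = predict_scores(model, tiny_dataset, batch_size=1)
        s64 = predict_scores(model, tiny_dataset, batch_size=64)
        for pid in s1:
            assert s1[pid] == pytest.approx(s64[pid], abs=1e-5)


class TestPersistence:
    def test_checkpoint_round_trip_bit_identical(self, tiny_dataset,
                                                 tiny_model_cfg,
                                                 mock_embedder, tmp_path):
        model = tiny_fit(tiny_dataset, tiny_model_cfg, mock_embedder, epochs=1)
        before = predict_scores(model, tiny_dataset)
        model.save(tmp_path / "ckpt")
        loaded = TrainedModel.load(tmp_path / "ckpt", embedder=mock_embedder)
        after = predict_scores(loaded, tiny_dataset)
        assert before == after

    def test_checkpoint_preserves_variant_and_config(self, tiny_dataset,
                                                     tiny_model_cfg,
                                                     mock_embedder, tmp_path):
        model = tiny_fit(tiny_dataset, tiny_model_cfg, mock_embedder,
                         mode="uniform", epochs=1)
        model.save(tmp_path / "ckpt")
        loaded = TrainedModel.load(tmp_path / "ckpt", embedder=mock_embedder)
        assert loaded.classifier.variant == VariantSpec.base()
        assert loaded.sampler_cfg.mode == "uniform"


class TestEmbeddings:
    def test_penultimate_width_and_determinism(self, tiny_dataset,
                                               tiny_model_cfg, mock_embedder):
        model = tiny_fit(tiny_dataset, tiny_model_cfg, mock_embedder, epochs=1)
        embs = export_embeddings(model, tiny_dataset)
        width = tiny_model_cfg.mlp_hidden[-1]
        assert all(v.shape == (width,) for v in embs.values())
        embs2 = export_embeddings(model, tiny_dataset)
        for pid in embs:
            np.testing.assert_array_equal(embs[pid], embs2[pid])

    def test_single_layer_mlp_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="penultimate"):
            nn.MLP(16, (), 2, rng)
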