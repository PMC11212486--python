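"""Desk-scale benchmark protocols run by the examples and acceptance checks.

These reproduce, at one-CPU scale, the two experiments the method is built
around: (i) hard-negative versus uniform sampling on an imbalanced synthetic
benchmark (1:100, mock embedder), and (ii) a fit on a perfectly separable
toy to sanity-check the optimisation loop end to end.

The desk configuration shrinks the feature extractor (64-wide model and
branch dimensions, 4 heads, 128-wide feed-forward, 16 conv channels,
128-dim mock residue states) while keeping the architecture, sampler and
training loop identical to the full-size defaults; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import LabeledDataset
from .embedders import MockEmbedder
from .evaluation import pr_curve_and_aupr
from .featurization import FeatureConfig, FeatureStore
from .hard_sampler import SamplerConfig
from .model import ModelConfig, TrainConfig, VariantSpec, fit, predict_scores
from .synthetic import benchmark_suite


def desk_model_config(pad_len: int = 30, residue_dim: int = 128) -> ModelConfig:
    """Scaled-down architecture for one-CPU runs (same topology as default)."""
    features = FeatureConfig(pad_len=pad_len, d_model=64, n_heads=4,
                             ffn_dim=128, branch_dim=64, conv_channels=16,
                             residue_dim=residue_dim)
    return ModelConfig(features=features, mlp_hidden=(64, 32))


@dataclass
class SamplingComparison:
    seed: int
    aupr_hard: float
    aupr_uniform: float
    prevalence: float


def run_sampling_benchmark(seed: int, K: int = 9, M: int = 3,
                           epochs: int = 12) -> SamplingComparison:
    """Train hard- and uniform-sampling models on one benchmark draw.

    Both runs share the generated 1:100 train/test pair, the scaled
    architecture, the parameter-init seed and the feature cache; only the
    negative-selection rule differs.
    """
    suite = benchmark_suite(seed=seed)
    model_cfg = desk_model_config()
    embedder = MockEmbedder(residue_dim=model_cfg.features.residue_dim,
                            seed=seed)
    store = FeatureStore(model_cfg.features, embedder=embedder)
    train_cfg = TrainConfig(batch_positives=32, epochs=epochs, seed=seed)
    labels = dict(zip(suite.test.ids, suite.test.labels))
    auprs = {}
    for mode in ("hard", "uniform"):
        variant = (VariantSpec.full() if mode == "hard" else
                   VariantSpec.base())
        sampler = SamplerConfig(K=K, M=M, seed=seed, mode=mode)
        model = fit(suite.train, variant, model_cfg=model_cfg,
                    train_cfg=train_cfg, sampler_cfg=sampler, store=store)
        scores = predict_scores(model, suite.test)
        auprs[mode] = pr_curve_and_aupr(scores, labels).auc
    prevalence = suite.test.n_positive() / len(suite.test)
    return SamplingComparison(seed=seed, aupr_hard=auprs["hard"],
                              aupr_uniform=auprs["uniform"],
                              prevalence=prevalence)


def separable_toy_dataset() -> LabeledDataset:
    """50 poly-arginine positives vs 500 poly-glycine negatives (10-mers)."""
    from .data_io import Peptide, POSITIVE, NEGATIVE
    peptides = ([Peptide(f"toy-pos-{i:03d}", "R" * 10) for i in range(50)]
                + [Peptide(f"toy-neg-{i:03d}", "G" * 10) for i in range(500)])
    labels = [POSITIVE] * 50 + [NEGATIVE] * 500
    return LabeledDataset(peptides=peptides, labels=labels)


def run_separable_toy(seed: int, max_epochs: int = 30) -> dict:
    """Fit on the separable toy; returns epochs used and training accuracy."""
    ds = separable_toy_dataset()
    model_cfg = desk_model_config(pad_len=10)
    embedder = MockEmbedder(residue_dim=model_cfg.features.residue_dim,
                            seed=seed)
    train_cfg = TrainConfig(batch_positives=25, epochs=max_epochs, seed=seed)
    sampler = SamplerConfig(K=3, M=3, seed=seed, mode="hard")
    model = fit(ds, VariantSpec.full(), model_cfg=model_cfg,
                train_cfg=train_cfg, sampler_cfg=sampler, embedder=embedder)
    epochs_used = len(model.train_log)
    scores = predict_scores(model, ds)
    pred = np.array([scores[i] >= 0.5 for i in ds.ids])
    truth = np.array([y == 1 for y in ds.labels])
    accuracy = float(np.mean(pred == truth))
    return {"accuracy": accuracy, "epochs": epochs_used}
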