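"""Classifier head and the hard-sampling training loop.

The model concatenates the active feature branches (sequential always;
fingerprint and pretrained optional, giving the named ablation variants)
and classifies with a small MLP (input -> 256 -> 64 -> 2, softmax).  Training
alternates two steps per batch until convergence: score a fresh candidate
pool of negatives with the current model, then take a cross-entropy gradient
step on the batch positives plus the selected (hard or uniform) negatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .data_io import LabeledDataset, NEGATIVE, POSITIVE
from .embedders import EmbedderHandle
from .featurization import (FeatureConfig, FeatureStore, LocalBranch,
                            PretrainedBranch, SequentialBranch, concat_features)
from .hard_sampler import (BatchPlan, SamplerConfig, assemble_batch,
                           draw_candidates, select_hard, uniform_select)


@dataclass(frozen=True)
class VariantSpec:
    """Which branches are active and how negatives are sampled."""

    use_fp: bool = True
    use_esm: bool = True
    sampling: str = "hard"  # "hard" | "uniform"

    def __post_init__(self):
        if self.sampling not in ("hard", "uniform"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")

    @property
    def n_branches(self) -> int:
        return 1 + int(self.use_fp) + int(self.use_esm)

    # the named ablation variants
    @classmethod
    def full(cls):
        return cls(use_fp=True, use_esm=True, sampling="hard")

    @classmethod
    def base(cls):
        """Uniform sampling; identical architecture to the full variant."""
        return cls(use_fp=True, use_esm=True, sampling="uniform")

    @classmethod
    def no_esm(cls, sampling="hard"):
        return cls(use_fp=True, use_esm=False, sampling=sampling)

    @classmethod
    def no_fp(cls, sampling="hard"):
        return cls(use_fp=False, use_esm=True, sampling=sampling)

    @classmethod
    def no_esm_fp(cls, sampling="hard"):
        return cls(use_fp=False, use_esm=False, sampling=sampling)

    @classmethod
    def named(cls, name: str) -> "VariantSpec":
        table = {"full": cls.full(), "base": cls.base(),
                 "no-esm": cls.no_esm(), "no-fp": cls.no_fp(),
                 "no-esm-fp": cls.no_esm_fp()}
        try:
            return table[name]
        except KeyError:
            raise ValueError(f"unknown variant {name!r}; "
                             f"choose from {sorted(table)}") from None


@dataclass
class TrainConfig:
    batch_positives: int = 32
    epochs: int = 100
    lr: float = 1e-3
    patience: int = 10        # early-stopping epochs without improvement
    min_delta: float = 1e-4   # minimum validation-loss improvement
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_positives, self.lr) <= 0 or self.epochs < 0:
            raise ValueError("train config values must be positive")


@dataclass
class ModelConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    mlp_hidden: tuple[int, ...] = (256, 64)


class CPPClassifier(nn.Module):
    """Three-branch feature extractor + MLP head."""

    def __init__(self, variant: VariantSpec, cfg: ModelConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.variant = variant
        self.cfg = cfg
        self.seed = seed
        fc = cfg.features
        self.seq_branch = SequentialBranch(fc, rng)
        self.fp_branch = LocalBranch(fc, rng) if variant.use_fp else None
        self.esm_branch = PretrainedBranch(fc, rng) if variant.use_esm else None
        self.mlp = nn.MLP(fc.branch_dim * variant.n_branches,
                          cfg.mlp_hidden, 2, rng)

    @property
    def input_width(self) -> int:
        return self.cfg.features.branch_dim * self.variant.n_branches

    def _features(self, batch: dict[str, np.ndarray]) -> nn.Tensor:
        branches = {"sequential": self.seq_branch(batch["token_ids"],
                                                  batch["mask"])}
        if self.fp_branch is not None:
            if "fp_bits" not in batch:
                raise ValueError("variant expects fingerprint inputs")
            branches["local"] = self.fp_branch(batch["fp_bits"])
        if self.esm_branch is not None:
            if "pooled_lm" not in batch:
                raise ValueError("variant expects pretrained inputs")
            branches["pretrained"] = self.esm_branch(batch["pooled_lm"])
        return concat_features(branches)

    def logits(self, batch: dict[str, np.ndarray]) -> nn.Tensor:
        return self.mlp(self._features(batch))

    def forward(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """Probability of the positive class per peptide, shape (B,)."""
        with nn.no_grad():
            probs = nn.softmax(self.logits(batch), axis=-1)
        return probs.data[:, POSITIVE]

    def penultimate(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        with nn.no_grad():
            return self.mlp.penultimate(self._features(batch)).data


@dataclass
class TrainedModel:
    """Classifier with its feature store, configs and training log."""

    classifier: CPPClassifier
    store: FeatureStore
    sampler_cfg: SamplerConfig
    train_cfg: TrainConfig
    train_log: list[dict] = field(default_factory=list)

    # ---- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = self.classifier.state_arrays()
        np.savez(directory / "weights.npz",
                 **{f"p{i}": a for i, a in enumerate(arrays)})
        meta = {
            "variant": asdict(self.classifier.variant),
            "model": {"mlp_hidden": list(self.classifier.cfg.mlp_hidden),
                      "features": asdict(self.classifier.cfg.features)},
            "sampler": asdict(self.sampler_cfg),
            "train": asdict(self.train_cfg),
            "seed": self.classifier.seed,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        (directory / "train_log.jsonl").write_text(
            "".join(json.dumps(rec) + "\n" for rec in self.train_log))

    @classmethod
    def load(cls, directory: str | Path,
             embedder: EmbedderHandle | None = None) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        variant = VariantSpec(**meta["variant"])
        fc = FeatureConfig(**meta["model"]["features"])
        cfg = ModelConfig(features=fc,
                          mlp_hidden=tuple(meta["model"]["mlp_hidden"]))
        clf = CPPClassifier(variant, cfg, meta["seed"])
        with np.load(directory / "weights.npz") as z:
            clf.load_state_arrays([z[f"p{i}"] for i in range(len(z.files))])
        store = FeatureStore(fc, embedder=embedder, use_fp=variant.use_fp,
                             use_pretrained=variant.use_esm)
        log_path = directory / "train_log.jsonl"
        log = ([json.loads(line) for line in log_path.read_text().splitlines()]
               if log_path.exists() else [])
        return cls(clf, store, SamplerConfig(**meta["sampler"]),
                   TrainConfig(**meta["train"]), log)


def init_model(variant: VariantSpec, seed: int,
               cfg: ModelConfig | None = None,
               embedder: EmbedderHandle | None = None,
               store: FeatureStore | None = None) -> TrainedModel:
    cfg = cfg or ModelConfig()
    clf = CPPClassifier(variant, cfg, seed)
    if store is None:
        store = FeatureStore(cfg.features, embedder=embedder,
                             use_fp=variant.use_fp,
                             use_pretrained=variant.use_esm)
    return TrainedModel(clf, store,
                        SamplerConfig(mode=variant.sampling, seed=seed),
                        TrainConfig(seed=seed))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _score_ids(model: TrainedModel, ids: list[str],
               batch_size: int = 256) -> dict[str, float]:
    out: dict[str, float] = {}
    for start in range(0, len(ids), batch_size):
        chunk = ids[start:start + batch_size]
        probs = model.classifier.forward(model.store.batch(chunk))
        out.update(zip(chunk, probs))
    return out


def plan_batch(model: TrainedModel, positive_ids: list[str],
               neg_pool: list[str], batch_index: int) -> BatchPlan:
    """Draw candidates, select negatives (hard or uniform), assemble T."""
    cfg = model.sampler_cfg
    candidates = draw_candidates(neg_pool, len(positive_ids), cfg, batch_index)
    if cfg.mode == "hard":
        scores = _score_ids(model, candidates)
        negs = select_hard(candidates, scores, len(positive_ids), cfg)
    else:
        negs = uniform_select(candidates, len(positive_ids), cfg, batch_index)
    return assemble_batch(positive_ids, negs, candidates)


def train_epoch(model: TrainedModel, dataset: LabeledDataset,
                optimizer: nn.Adam, epoch: int) -> dict:
    """One pass over shuffled positive batches; returns the epoch log record."""
    pos_ids = [p.id for p, y in zip(dataset.peptides, dataset.labels)
               if y == POSITIVE]
    neg_ids = [p.id for p, y in zip(dataset.peptides, dataset.labels)
               if y == NEGATIVE]
    if not pos_ids:
        raise ValueError("dataset has no positives")
    model.store.add_peptides(dataset.peptides)
    rng = np.random.default_rng([model.train_cfg.seed, epoch])
    order = rng.permutation(len(pos_ids))
    bp = model.train_cfg.batch_positives
    losses = []
    for b, start in enumerate(range(0, len(pos_ids), bp)):
        batch_pos = [pos_ids[i] for i in order[start:start + bp]]
        plan = plan_batch(model, batch_pos, neg_ids,
                          batch_index=epoch * 100_000 + b)
        batch = model.store.batch(list(plan.training_ids))
        logits = model.classifier.logits(batch)
        loss = nn.cross_entropy(logits, plan.labels())
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        losses.append(float(loss.data))
    return {"epoch": epoch, "mean_loss": float(np.mean(losses)),
            "n_batches": len(losses)}


def fit(dataset: LabeledDataset, variant: VariantSpec,
        model_cfg: ModelConfig | None = None,
        train_cfg: TrainConfig | None = None,
        sampler_cfg: SamplerConfig | None = None,
        embedder: EmbedderHandle | None = None,
        validation: LabeledDataset | None = None,
        store: FeatureStore | None = None) -> TrainedModel:
    """Train until the early-stopping rule or the epoch budget.

    With a validation set, training stops once validation loss fails to
    improve by ``min_delta`` for ``patience`` consecutive epochs and the
    best-validation parameters are restored; without one, the final state is
    returned.  ``epochs=0`` returns the initialized model untouched.
    """
    train_cfg = train_cfg or TrainConfig()
    model = init_model(variant, train_cfg.seed, model_cfg, embedder, store)
    model.train_cfg = train_cfg
    if sampler_cfg is not None:
        if sampler_cfg.mode != variant.sampling:
            raise ValueError("sampler mode disagrees with variant.sampling")
        model.sampler_cfg = sampler_cfg
    model.store.add_peptides(dataset.peptides)
    optimizer = nn.Adam(model.classifier.parameters(), lr=train_cfg.lr)
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    stall = 0
    for epoch in range(train_cfg.epochs):
        record = train_epoch(model, dataset, optimizer, epoch)
        if validation is not None:
            val_loss = _validation_loss(model, validation)
            record["val_loss"] = val_loss
            if val_loss < best_val - train_cfg.min_delta:
                best_val = val_loss
                best_state = [a.copy() for a in model.classifier.state_arrays()]
                stall = 0
            else:
                stall += 1
        model.train_log.append(record)
        if validation is not None and stall >= train_cfg.patience:
            break
    if best_state is not None:
        model.classifier.load_state_arrays(best_state)
    return model


def _validation_loss(model: TrainedModel, validation: LabeledDataset) -> float:
    model.store.add_peptides(validation.peptides)
    ids = validation.ids
    labels = np.asarray(validation.labels)
    total, n = 0.0, 0
    with nn.no_grad():
        for start in range(0, len(ids), 256):
            chunk = ids[start:start + 256]
            logits = model.classifier.logits(model.store.batch(chunk))
            loss = nn.cross_entropy(logits, labels[start:start + 256])
            total += float(loss.data) * len(chunk)
            n += len(chunk)
    return total / n


def predict_scores(model: TrainedModel, dataset: LabeledDataset,
                   batch_size: int = 256) -> dict[str, float]:
    """Positive-class probability per peptide, keyed by id."""
    model.store.add_peptides(dataset.peptides)
    return _score_ids(model, dataset.ids, batch_size)


def export_embeddings(model: TrainedModel,
                      dataset: LabeledDataset) -> dict[str, np.ndarray]:
    """Penultimate-MLP-layer vector per peptide (for 2-D projection)."""
    model.store.add_peptides(dataset.peptides)
    out: dict[str, np.ndarray] = {}
    for start in range(0, len(dataset), 256):
        chunk = dataset.ids[start:start + 256]
        vecs = model.classifier.penultimate(model.store.batch(chunk))
        out.update(zip(chunk, vecs))
    return out
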