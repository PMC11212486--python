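"""YAML run configuration shared by the CLI subcommands.

A run config merges ``data``, ``sampler``, ``model``, ``train`` and ``eval``
sections with a global seed; the resolved config is serialized into every
output directory for provenance.  The global seed fans out to named
sub-seeds (split, sampler, init) so each component is independently
reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import yaml

from .featurization import FeatureConfig
from .hard_sampler import SamplerConfig
from .model import ModelConfig, TrainConfig


def subseed(global_seed: int, name: str) -> int:
    """Stable named sub-seed derived from the global seed (< 2**31)."""
    digest = hashlib.blake2b(f"{global_seed}:{name}".encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2 ** 31)


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def resolve(cfg: dict, seed: int) -> dict:
    """Fill defaults and fan out seeds; returns a plain serialisable dict."""
    sampler = SamplerConfig(seed=subseed(seed, "sampler"),
                            **cfg.get("sampler", {}))
    features = FeatureConfig(**cfg.get("features", {}))
    model = ModelConfig(features=features,
                        mlp_hidden=tuple(cfg.get("model", {})
                                         .get("mlp_hidden", (256, 64))))
    train = TrainConfig(seed=subseed(seed, "init"), **cfg.get("train", {}))
    return {
        "seed": seed,
        "sampler": asdict(sampler),
        "model": {"mlp_hidden": list(model.mlp_hidden),
                  "features": asdict(features)},
        "train": asdict(train),
        "data": cfg.get("data", {}),
        "eval": cfg.get("eval", {"recalls": [0.6, 0.7]}),
    }


def dump_config(resolved: dict, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "run_config.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True))
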