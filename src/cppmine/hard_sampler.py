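"""Hard negative sampling for extremely imbalanced peptide classification.

With ~1000 unlabeled negatives per known positive, training on everything is
both wasteful and dominated by easy negatives.  Instead, for every batch of
positives P_batch the sampler

1. draws a uniform candidate pool N_sample of size ``K x |P_batch|`` from the
   negative set;
2. scores the candidates with the current model and keeps the ``M x
   |P_batch|`` with the highest positive probability (N_hard), the negatives
   the model currently finds hardest;
3. trains on the disjoint union ``T = P_batch ∪ N_hard`` (class ratio 1:M).

``K`` controls how close the kept negatives sit to the decision boundary
(larger pools contain harder negatives); ``M`` fixes the realised class ratio
inside each batch.  Defaults K=9, M=3.  The ``uniform`` mode skips scoring
and keeps a random M x |P_batch| subset — the baseline the hard variant is
compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class SamplerConfig:
    K: int = 9
    M: int = 3
    seed: int = 0
    mode: str = "hard"  # "hard" | "uniform"

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if not (1 <= self.M <= self.K):
            raise ValueError(f"need 1 <= M <= K, got M={self.M}, K={self.K}")
        if self.mode not in ("hard", "uniform"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")


@dataclass(frozen=True)
class BatchPlan:
    """One batch's ids: positives, candidates, selected hard set, union T."""

    positive_ids: tuple[str, ...]
    candidate_ids: tuple[str, ...]
    hard_ids: tuple[str, ...]
    training_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if set(self.hard_ids) - set(self.candidate_ids):
            raise ValueError("hard_ids must be a subset of candidate_ids")
        overlap = set(self.positive_ids) & set(self.hard_ids)
        if overlap:
            raise ValueError(f"positive/negative id overlap: {sorted(overlap)[:5]}")
        expected = tuple(self.positive_ids) + tuple(self.hard_ids)
        if not self.training_ids:
            object.__setattr__(self, "training_ids", expected)
        elif tuple(self.training_ids) != expected:
            raise ValueError("training_ids must be positives followed by hards")

    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positive_ids) + [0] * len(self.hard_ids))


def _rng_for(cfg: SamplerConfig, batch_index: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, batch index)
    return np.random.default_rng([cfg.seed, batch_index])


def draw_candidates(neg_pool: Sequence[str], n_pos: int, cfg: SamplerConfig,
                    batch_index: int = 0) -> list[str]:
    """Uniform sample without replacement of size ``min(K*n_pos, |pool|)``.

    Deterministic for a fixed (seed, batch_index).  A pool smaller than
    ``K*n_pos`` is clamped with a warning rather than raising, so small
    synthetic runs stay viable.
    """
    if len(neg_pool) == 0:
        raise ValueError("negative pool is empty")
    want = cfg.K * n_pos
    if want > len(neg_pool):
        warnings.warn(
            f"candidate pool clamped: wanted {want}, pool has {len(neg_pool)}",
            stacklevel=2)
        want = len(neg_pool)
    rng = _rng_for(cfg, batch_index)
    idx = rng.choice(len(neg_pool), size=want, replace=False)
    return [neg_pool[i] for i in idx]


def select_hard(candidate_ids: Sequence[str], scores: Mapping[str, float],
                n_pos: int, cfg: SamplerConfig) -> list[str]:
    """Top ``M*n_pos`` candidates by positive-class probability.

    Ties are broken by ascending id for reproducibility; if there are fewer
    candidates than requested, all are taken with a warning.
    """
    want = cfg.M * n_pos
    missing = [c for c in candidate_ids if c not in scores]
    if missing:
        raise KeyError(f"candidates without scores: {missing[:5]}")
    for c in candidate_ids:
        if not (0.0 <= scores[c] <= 1.0):
            raise ValueError(f"score for {c!r} outside [0, 1]: {scores[c]}")
    if want > len(candidate_ids):
        warnings.warn(
            f"fewer candidates ({len(candidate_ids)}) than requested hard "
            f"negatives ({want}); taking all", stacklevel=2)
        want = len(candidate_ids)
    ranked = sorted(candidate_ids, key=lambda c: (-scores[c], c))
    return ranked[:want]


def uniform_select(candidate_ids: Sequence[str], n_pos: int,
                   cfg: SamplerConfig, batch_index: int = 0) -> list[str]:
    """Uniform ``M*n_pos`` subset of the candidates, ignoring any scores."""
    want = cfg.M * n_pos
    if want > len(candidate_ids):
        warnings.warn(
            f"fewer candidates ({len(candidate_ids)}) than requested "
            f"({want}); taking all", stacklevel=2)
        want = len(candidate_ids)
    # separate stream from draw_candidates so the two draws are independent
    rng = np.random.default_rng([cfg.seed, batch_index, 1])
    idx = rng.choice(len(candidate_ids), size=want, replace=False)
    return [candidate_ids[i] for i in idx]


def assemble_batch(positive_ids: Sequence[str],
                   hard_ids: Sequence[str],
                   candidate_ids: Sequence[str] | None = None) -> BatchPlan:
    """Union ``T = P_batch ∪ N_hard``; raises on any id overlap (leak guard)."""
    return BatchPlan(
        positive_ids=tuple(positive_ids),
        candidate_ids=tuple(candidate_ids if candidate_ids is not None
                            else hard_ids),
        hard_ids=tuple(hard_ids),
    )
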