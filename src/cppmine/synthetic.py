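"""Synthetic peptide datasets with planted cell-penetration-like signal.

Real CPP collections are short (5-30 residues), cationic and enriched in
arginine, lysine and tryptophan; functional CPPs carry at least two
arginines.  The generator reproduces exactly that statistical structure so
the whole pipeline — curation, featurization, hard sampling, training,
imbalanced evaluation — is testable without downloads:

* positives draw residues from a mixture ``(1-s) * uniform + s * motif``
  where the motif distribution concentrates on R/K/W (optionally F) and
  ``s`` is the signal strength in [0, 1]; a >= 2 arginine constraint is
  enforced;
* negatives (the "unlabeled" pool) draw i.i.d. from the uniform background;
* the negative:positive ratio is configurable up to 1:1000.

At ``s = 0`` the two classes differ only by the arginine constraint; at
``s = 1`` positives are drawn from the motif distribution alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import LabeledDataset, NATURAL_AA, NEGATIVE, POSITIVE, Peptide

#: Motif residue distribution: concentrated on the residues reported as
#: discriminative for membrane penetration (R, K, W, with a little F).
MOTIF_DISTRIBUTION = {"R": 0.45, "K": 0.25, "W": 0.20, "F": 0.10}


@dataclass(frozen=True)
class SyntheticSpec:
    n_pos: int = 50
    ratio: int = 100                      # negatives per positive
    length_range: tuple[int, int] = (5, 30)
    min_arginines: int = 2
    signal_strength: float = 1.0
    seed: int = 0
    label_noise: float = 0.0              # fraction of latent CPPs in the pool

    def __post_init__(self):
        lo, hi = self.length_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("length_range must satisfy 1 <= lo <= hi <= 50")
        if lo < self.min_arginines:
            raise ValueError(
                f"min length {lo} cannot hold {self.min_arginines} arginines")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must be in [0, 1]")
        if self.n_pos < 1 or self.ratio < 0:
            raise ValueError("n_pos must be >= 1 and ratio >= 0")


def _positive_probs(signal_strength: float) -> np.ndarray:
    background = np.full(len(NATURAL_AA), 1.0 / len(NATURAL_AA))
    motif = np.zeros(len(NATURAL_AA))
    for aa, p in MOTIF_DISTRIBUTION.items():
        motif[NATURAL_AA.index(aa)] = p
    return (1.0 - signal_strength) * background + signal_strength * motif


def _draw_sequence(rng: np.random.Generator, length: int,
                   probs: np.ndarray) -> str:
    idx = rng.choice(len(NATURAL_AA), size=length, p=probs)
    return "".join(NATURAL_AA[i] for i in idx)


def _draw_positive(rng: np.random.Generator, length: int, probs: np.ndarray,
                   min_r: int, max_tries: int = 1000) -> str:
    for _ in range(max_tries):
        seq = _draw_sequence(rng, length, probs)
        if seq.count("R") >= min_r:
            return seq
    # force-place arginines at random positions (vanishingly rare fallback)
    seq = list(_draw_sequence(rng, length, probs))
    for pos in rng.choice(length, size=min_r, replace=False):
        seq[pos] = "R"
    return "".join(seq)


def generate(spec: SyntheticSpec, id_prefix: str = "syn") -> LabeledDataset:
    """Labeled dataset with ``n_pos`` positives and ``ratio * n_pos`` negatives."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    pos_probs = _positive_probs(spec.signal_strength)
    neg_probs = _positive_probs(0.0)
    peptides: list[Peptide] = []
    labels: list[int] = []
    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        peptides.append(Peptide(f"{id_prefix}-pos-{i:06d}",
                                _draw_positive(rng, length, pos_probs,
                                               spec.min_arginines)))
        labels.append(POSITIVE)
    n_neg = spec.n_pos * spec.ratio
    n_latent = int(round(spec.label_noise * n_neg))
    for i in range(n_neg):
        length = int(rng.integers(lo, hi + 1))
        if i < n_latent:  # latent CPPs mislabelled as negative
            seq = _draw_positive(rng, length, pos_probs, spec.min_arginines)
        else:
            seq = _draw_sequence(rng, length, neg_probs)
        peptides.append(Peptide(f"{id_prefix}-neg-{i:06d}", seq))
        labels.append(NEGATIVE)
    return LabeledDataset(peptides=peptides, labels=labels)


@dataclass(frozen=True)
class BenchmarkSuite:
    """Fixed train/test pair at 1:100 used by the acceptance runs."""

    train: LabeledDataset
    test: LabeledDataset
    spec_train: SyntheticSpec = field(repr=False, default=None)
    spec_test: SyntheticSpec = field(repr=False, default=None)


def benchmark_suite(seed: int = 0, signal_strength: float = 1.0,
                    n_train_pos: int = 200, n_test_pos: int = 50,
                    ratio: int = 100) -> BenchmarkSuite:
    """Desk-scale imbalanced benchmark: 200/50 train/test positives at 1:100.

    Train and test are generated from disjoint seeds and id prefixes; the
    test set keeps the same imbalance ratio as training, mirroring the
    independent-test-set protocol of the 1:1000 benchmark at a size that
    runs on one CPU.
    """
    spec_train = SyntheticSpec(n_pos=n_train_pos, ratio=ratio,
                               signal_strength=signal_strength, seed=seed * 2 + 1)
    spec_test = SyntheticSpec(n_pos=n_test_pos, ratio=ratio,
                              signal_strength=signal_strength, seed=seed * 2 + 2)
    return BenchmarkSuite(
        train=generate(spec_train, id_prefix=f"bench{seed}-train"),
        test=generate(spec_test, id_prefix=f"bench{seed}-test"),
        spec_train=spec_train, spec_test=spec_test)
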