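"""The three per-peptide feature branches and their concatenation.

A peptide is represented by up to three 512-wide embeddings:

* **sequential** — token ids plus sinusoidal positional encodings through a
  transformer encoder layer, mask-aware mean-pooled over real positions;
* **local** — the 1024-bit radius-2 Morgan fingerprint of the peptide
  treated as a molecule, passed through a 1-D convolution, global max-pool
  and a dense projection;
* **pretrained** — per-residue language-model embeddings mean-pooled over
  the true length and densely projected.

Active branches are concatenated in the fixed order (sequential, local,
pretrained) and fed to the classifier head in :mod:`cppmine.model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data_io import NATURAL_AA, Peptide
from .embedders import EmbedderHandle
from .morgan import fingerprint_sequence

PAD_ID = 0
TOKEN_TABLE = {aa: i + 1 for i, aa in enumerate(NATURAL_AA)}
VOCAB_SIZE = len(NATURAL_AA) + 1  # + padding id


@dataclass(frozen=True)
class TokenSequence:
    token_ids: np.ndarray  # (pad_len,) int64
    mask: np.ndarray       # (pad_len,) bool, True = real residue

    @property
    def pad_len(self) -> int:
        return self.token_ids.shape[0]

    @property
    def length(self) -> int:
        return int(self.mask.sum())


def tokenize_pad(p: Peptide | str, pad_len: int = 50) -> TokenSequence:
    """Map residues to integer ids via a fixed table and pad to ``pad_len``."""
    seq = p.sequence if isinstance(p, Peptide) else p
    if len(seq) > pad_len:
        raise ValueError(f"sequence length {len(seq)} exceeds pad_len {pad_len}")
    ids = np.full(pad_len, PAD_ID, dtype=np.int64)
    try:
        ids[:len(seq)] = [TOKEN_TABLE[a] for a in seq]
    except KeyError as exc:
        raise ValueError(f"non-natural residue {exc} in {seq!r}") from exc
    mask = np.zeros(pad_len, dtype=bool)
    mask[:len(seq)] = True
    return TokenSequence(ids, mask)


def positional_encoding(pad_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional table, shape ``(pad_len, d_model)``.

    ``table[pos, 2i] = sin(pos / 10000^(2i/d_model))`` and
    ``table[pos, 2i+1] = cos(pos / 10000^(2i/d_model))``.
    """
    if d_model % 2:
        raise ValueError("d_model must be even")
    if pad_len < 1:
        raise ValueError("pad_len must be >= 1")
    pos = np.arange(pad_len)[:, None]
    i2 = np.arange(0, d_model, 2)[None, :]
    angle = pos / np.power(10000.0, i2 / d_model)
    table = np.empty((pad_len, d_model))
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle)
    return table


@dataclass
class FeatureConfig:
    """Hyperparameters of the feature branches.

    Defaults are the reference architecture: 512-wide branch outputs, one 8-head encoder layer with a
    2048-wide feed-forward, a kernel-8/64-channel fingerprint convolution,
    and 1280-dim pretrained residue states.
    """

    pad_len: int = 50
    d_model: int = 512
    n_heads: int = 8
    n_layers: int = 1
    ffn_dim: int = 2048
    branch_dim: int = 512
    fp_bits: int = 1024
    fp_radius: int = 2
    conv_kernel: int = 8
    conv_channels: int = 64
    residue_dim: int = 1280


class SequentialBranch(nn.Module):
    """Token embedding + sinusoidal positions -> transformer -> mean pool."""

    def __init__(self, cfg: FeatureConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.embedding = nn.Embedding(VOCAB_SIZE, cfg.d_model, rng)
        self.pos_table = positional_encoding(cfg.pad_len, cfg.d_model)
        self.encoder = [nn.TransformerEncoderLayer(cfg.d_model, cfg.n_heads,
                                                   cfg.ffn_dim, rng)
                        for _ in range(cfg.n_layers)]
        self.project = (nn.Linear(cfg.d_model, cfg.branch_dim, rng)
                        if cfg.d_model != cfg.branch_dim else None)

    def __call__(self, token_ids: np.ndarray, mask: np.ndarray) -> nn.Tensor:
        x = self.embedding(token_ids) + nn.Tensor(self.pos_table[None, :, :])
        for layer in self.encoder:
            x = layer(x, mask)
        pooled = nn.masked_mean_pool(x, mask)
        return self.project(pooled) if self.project is not None else pooled


class LocalBranch(nn.Module):
    """Fingerprint bits -> 1-D conv -> global max pool -> dense projection."""

    def __init__(self, cfg: FeatureConfig, rng: np.random.Generator):
        self.conv = nn.Conv1dMaxPool(cfg.conv_kernel, cfg.conv_channels, rng)
        self.fc = nn.Linear(cfg.conv_channels, cfg.branch_dim, rng)

    def __call__(self, bits: np.ndarray) -> nn.Tensor:
        return self.fc(self.conv(bits))


class PretrainedBranch(nn.Module):
    """Mean-pooled language-model residue states -> dense projection.

    The embedder itself is frozen; only the projection trains.  Pooling
    divides by the true sequence length, so padding never enters.
    """

    def __init__(self, cfg: FeatureConfig, rng: np.random.Generator):
        self.fc = nn.Linear(cfg.residue_dim, cfg.branch_dim, rng)

    def __call__(self, pooled_embeddings: np.ndarray) -> nn.Tensor:
        return self.fc(nn.Tensor(pooled_embeddings))


BRANCH_ORDER = ("sequential", "local", "pretrained")


def concat_features(branches: dict[str, nn.Tensor]) -> nn.Tensor:
    """Concatenate active branch embeddings in the fixed canonical order."""
    active = [branches[name] for name in BRANCH_ORDER if name in branches]
    if not active:
        raise ValueError("at least one feature branch must be active")
    if len(active) == 1:
        return active[0]
    return nn.concat(active, axis=-1)


def mean_pool_embedding(p: Peptide | str, embedder: EmbedderHandle) -> np.ndarray:
    """``x = (sum_i H_i) / l`` over the embedder's per-residue matrix."""
    seq = p.sequence if isinstance(p, Peptide) else p
    try:
        mat = embedder.embed(seq)
    except Exception as exc:
        pid = p.id if isinstance(p, Peptide) else "<raw>"
        raise RuntimeError(f"embedder failed for peptide {pid!r}") from exc
    if mat.shape[0] != len(seq):
        raise ValueError(
            f"embedder returned {mat.shape[0]} rows for length {len(seq)}")
    return mat.mean(axis=0)


@dataclass
class FeatureStore:
    """Lazy per-peptide cache of the frozen (non-trainable) inputs.

    Token ids and masks, fingerprint bit vectors and pooled pretrained
    embeddings are pure functions of the sequence, so they are computed once
    per unique id and re-used across the many batches of a training run.
    """

    cfg: FeatureConfig
    embedder: EmbedderHandle | None = None
    use_fp: bool = True
    use_pretrained: bool = True
    # caches keyed by SEQUENCE: duplicated sequences share one computation
    _tokens: dict[str, TokenSequence] = field(default_factory=dict)
    _fps: dict[str, np.ndarray] = field(default_factory=dict)
    _pooled: dict[str, np.ndarray] = field(default_factory=dict)
    _seqs: dict[str, str] = field(default_factory=dict)  # id -> sequence

    def add_peptides(self, peptides) -> None:
        for p in peptides:
            self._seqs[p.id] = p.sequence

    def _sequence(self, pid: str) -> str:
        try:
            return self._seqs[pid]
        except KeyError:
            raise KeyError(f"unknown peptide id {pid!r}; call add_peptides") \
                from None

    def batch(self, ids: list[str]) -> dict[str, np.ndarray]:
        """Stack the frozen inputs for a batch of peptide ids."""
        toks, masks, fps, pooled = [], [], [], []
        for pid in ids:
            seq = self._sequence(pid)
            if seq not in self._tokens:
                self._tokens[seq] = tokenize_pad(seq, self.cfg.pad_len)
            t = self._tokens[seq]
            toks.append(t.token_ids)
            masks.append(t.mask)
            if self.use_fp:
                if seq not in self._fps:
                    self._fps[seq] = fingerprint_sequence(
                        seq, self.cfg.fp_radius, self.cfg.fp_bits
                    ).bits.astype(np.float64)
                fps.append(self._fps[seq])
            if self.use_pretrained:
                if self.embedder is None:
                    raise ValueError("pretrained branch active but no embedder")
                if seq not in self._pooled:
                    self._pooled[seq] = mean_pool_embedding(
                        Peptide(pid, seq), self.embedder)
                pooled.append(self._pooled[seq])
        out = {"token_ids": np.stack(toks), "mask": np.stack(masks)}
        if self.use_fp:
            out["fp_bits"] = np.stack(fps)
        if self.use_pretrained:
            out["pooled_lm"] = np.stack(pooled)
        return out
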