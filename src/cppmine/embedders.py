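"""Per-residue embedding backends for the pretrained-feature branch.

The classifier consumes an ``length x residue_dim`` matrix per peptide from a
pluggable embedder.  The production configuration uses a frozen ESM-2
protein language model (650M parameters, 1280-dim per-residue states); desk
work and the test suite use :class:`MockEmbedder`, a deterministic stand-in
that derives each row from a seeded hash of the residue and its immediate
sequence window.  Both satisfy the same contract:

* ``embed(sequence)`` returns a float array of shape ``(len(sequence),
  residue_dim)``;
* the output is a pure function of the sequence (and the embedder's own
  fixed configuration).
"""

from __future__ import annotations

import hashlib
from typing import Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class EmbedderHandle(Protocol):
    name: str
    residue_dim: int

    def embed(self, sequence: str) -> np.ndarray: ...


class MockEmbedder:
    """Deterministic synthetic per-residue embeddings (no model download).

    Row ``i`` is drawn from a normal generator seeded by a stable hash of
    ``(seed, sequence[i-1:i+2])`` — the residue plus its one-residue context
    window — so identical windows map to identical rows, embeddings are
    reproducible across processes, and nearby sequence context influences
    the representation the way a tiny language model's would.
    """

    def __init__(self, residue_dim: int = 1280, seed: int = 0,
                 name: str = "mock"):
        self.name = name
        self.residue_dim = int(residue_dim)
        self.seed = int(seed)

    def _row_seed(self, window: str) -> int:
        digest = hashlib.blake2b(f"{self.seed}:{window}".encode(),
                                 digest_size=4).digest()
        return int.from_bytes(digest, "little")

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        out = np.empty((len(sequence), self.residue_dim))
        for i in range(len(sequence)):
            window = sequence[max(0, i - 1):i + 2]
            rng = np.random.default_rng(self._row_seed(window))
            out[i] = rng.standard_normal(self.residue_dim)
        return out


class ConstantRowEmbedder:
    """Every residue maps to the same fixed row; used to test mean pooling."""

    def __init__(self, row: np.ndarray, name: str = "constant"):
        self.row = np.asarray(row, dtype=np.float64)
        self.residue_dim = self.row.shape[0]
        self.name = name

    def embed(self, sequence: str) -> np.ndarray:
        return np.tile(self.row, (len(sequence), 1))


class Esm2Embedder:
    """Frozen ESM-2 backend (esm2_t33_650M_UR50D, 1280-dim residue states).

    Requires the optional ``fair-esm`` dependency and a weight download;
    instantiate only in environments where those are available.
    """

    def __init__(self, model_name: str = "esm2_t33_650M_UR50D"):
        try:
            import esm  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the ESM-2 backend needs the optional 'fair-esm' package; "
                "install it (pip install fair-esm) or use MockEmbedder"
            ) from exc
        self.name = model_name
        model, alphabet = getattr(esm.pretrained, model_name)()
        model.eval()
        self._model = model
        self._batch_converter = alphabet.get_batch_converter()
        self.residue_dim = model.embed_dim

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover
        import torch  # type: ignore
        _, _, tokens = self._batch_converter([("query", sequence)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[self._model.num_layers])
        rep = out["representations"][self._model.num_layers][0]
        return rep[1:len(sequence) + 1].numpy()  # strip BOS/EOS


def get_embedder(kind: str = "mock", residue_dim: int = 1280,
                 seed: int = 0) -> EmbedderHandle:
    if kind == "mock":
        return MockEmbedder(residue_dim=residue_dim, seed=seed)
    if kind == "esm2":
        return Esm2Embedder()
    raise ValueError(f"unknown embedder kind: {kind!r}")
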