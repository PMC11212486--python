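"""Peptide dataset reading, validation, curation and splitting.

Mirrors the curation applied to real CPP benchmark collections: keep only
sequences over the 20 proteinogenic residues, drop peptides longer than 50
residues (the working definition of a peptide), collapse near-duplicate
sequences with a greedy identity clustering, then assemble imbalanced
positive/unlabeled splits at a configurable negative:positive ratio.

The redundancy filter is an approximate stand-in for CD-HIT: pairwise
identity is the number of matched columns in a global Needleman-Wunsch
alignment (match 1, mismatch 0, linear gap -1) divided by the length of the
shorter sequence, and retention is greedy longest-first.  Exact CD-HIT
cluster parity is not a goal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold

NATURAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_NATURAL_SET = frozenset(NATURAL_AA)

POSITIVE = 1
NEGATIVE = 0  # "unlabeled, treated as negative"


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class Peptide:
    """An identified amino-acid sequence (uppercase, one-letter codes)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CurationReport:
    n_input: int = 0
    n_removed_length: int = 0
    n_removed_nonnatural: int = 0
    n_removed_redundant: int = 0

    @property
    def n_output(self) -> int:
        return (self.n_input - self.n_removed_length
                - self.n_removed_nonnatural - self.n_removed_redundant)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["n_output"] = self.n_output
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class LabeledDataset:
    """Ordered peptides with optional binary labels and split tags.

    ``labels[i]`` is 1 (positive CPP), 0 (unlabeled/negative) or None.
    ``split[i]`` is an arbitrary tag such as ``train``/``test``/``fold-3``.
    """

    peptides: list[Peptide] = field(default_factory=list)
    labels: list[int | None] = field(default_factory=list)
    split: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = [None] * len(self.peptides)
        if not self.split:
            self.split = [None] * len(self.peptides)
        if not (len(self.peptides) == len(self.labels) == len(self.split)):
            raise ValueError("peptides, labels and split must be equally long")
        ids = [p.id for p in self.peptides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peptide ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def n_positive(self) -> int:
        return sum(1 for y in self.labels if y == POSITIVE)

    def n_negative(self) -> int:
        return sum(1 for y in self.labels if y == NEGATIVE)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            peptides=[self.peptides[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            split=[self.split[i] for i in indices],
        )

    def with_labels(self, label: int) -> "LabeledDataset":
        return LabeledDataset(peptides=list(self.peptides),
                              labels=[label] * len(self),
                              split=list(self.split))

    def select_split(self, tag: str) -> "LabeledDataset":
        return self.subset([i for i, s in enumerate(self.split) if s == tag])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "sequence": self.sequences,
            "label": self.labels,
            "split": self.split,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        peptides = [Peptide(str(r.id), str(r.sequence).upper())
                    for r in df.itertuples()]
        labels = ([None if pd.isna(v) else int(v) for v in df["label"]]
                  if "label" in df else [None] * len(df))
        split = ([None if pd.isna(v) else str(v) for v in df["split"]]
                 if "split" in df else [None] * len(df))
        return cls(peptides=peptides, labels=labels, split=split)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> LabeledDataset:
    """Read a FASTA file into an unlabeled dataset.

    Record ids are headers up to the first whitespace; wrapped sequence lines
    are concatenated and uppercased.  A header with no sequence raises
    :class:`FastaParseError`; an empty file yields an empty dataset with a
    warning.
    """
    path = Path(path)
    peptides = []
    with path.open() as handle:
        first = handle.read(1)
        if first == "":
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return LabeledDataset()
        if first != ">":
            raise FastaParseError(f"{path}: line 1: expected '>' header")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            if not seq:
                raise FastaParseError(
                    f"{path}: record '{record.id}' has no sequence")
            peptides.append(Peptide(record.id, seq))
    return LabeledDataset(peptides=peptides)


def write_fasta(ds: LabeledDataset, path: str | Path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="")
               for p in ds.peptides]
    SeqIO.write(records, str(path), "fasta")


def read_table(path: str | Path) -> LabeledDataset:
    """Read a CSV/TSV with columns id,sequence[,label,split]."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "sequence": str})
    if "id" not in df or "sequence" not in df:
        raise ValueError(f"{path}: need columns 'id' and 'sequence'")
    return LabeledDataset.from_frame(df)


def write_table(ds: LabeledDataset, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    ds.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Validation & filtering
# ---------------------------------------------------------------------------

def validate_natural(p: Peptide | str) -> bool:
    """True iff non-empty and every residue is one of the 20 natural letters."""
    seq = p.sequence if isinstance(p, Peptide) else p
    return bool(seq) and set(seq) <= _NATURAL_SET


def natural_filter(ds: LabeledDataset,
                   report: CurationReport | None = None) -> LabeledDataset:
    keep = [i for i, p in enumerate(ds.peptides) if validate_natural(p)]
    if report is not None:
        report.n_removed_nonnatural += len(ds) - len(keep)
    return ds.subset(keep)


def length_filter(ds: LabeledDataset, max_len: int = 50,
                  report: CurationReport | None = None) -> LabeledDataset:
    """Retain peptides with length <= ``max_len`` (default 50), order kept."""
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    keep = [i for i, p in enumerate(ds.peptides) if p.length <= max_len]
    if report is not None:
        report.n_removed_length += len(ds) - len(keep)
    return ds.subset(keep)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global alignment of ``a`` and ``b``.

    Needleman-Wunsch with match 1, mismatch 0, linear gap -1; identity is
    matched columns divided by the shorter length (CD-HIT-like convention).
    Traceback ties prefer diagonal, then up, then left, making the count
    deterministic.
    """
    if not a or not b:
        return 0.0
    n, m = len(a), len(b)
    NEG = -10 ** 9
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    matches = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = -np.arange(n + 1)
    score[0, :] = -np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (1 if ai == b[j - 1] else 0)
            up = score[i - 1, j] - 1
            left = score[i, j - 1] - 1
            best = max(diag, up, left)
            score[i, j] = best
            if best == diag:
                matches[i, j] = matches[i - 1, j - 1] + (1 if ai == b[j - 1] else 0)
            elif best == up:
                matches[i, j] = matches[i - 1, j]
            else:
                matches[i, j] = matches[i, j - 1]
    return matches[n, m] / min(n, m)


def greedy_redundancy_filter(
        ds: LabeledDataset, identity_threshold: float = 0.80,
        report: CurationReport | None = None) -> LabeledDataset:
    """Greedy longest-first identity clustering (approximate CD-HIT stand-in).

    Sequences are visited longest first (ties: lexicographic by sequence then
    id); each is kept unless it has identity >= ``identity_threshold`` with an
    already-kept sequence.
    """
    order = sorted(range(len(ds)),
                   key=lambda i: (-ds.peptides[i].length,
                                  ds.peptides[i].sequence, ds.peptides[i].id))
    kept: list[int] = []
    kept_seqs: list[str] = []
    seen_exact: set[str] = set()
    for i in order:
        seq = ds.peptides[i].sequence
        if seq in seen_exact:
            continue
        redundant = any(pairwise_identity(seq, other) >= identity_threshold
                        for other in kept_seqs)
        if not redundant:
            kept.append(i)
            kept_seqs.append(seq)
            seen_exact.add(seq)
    if report is not None:
        report.n_removed_redundant += len(ds) - len(kept)
    return ds.subset(sorted(kept))


def drop_conflicting(pos: LabeledDataset,
                     neg: LabeledDataset) -> tuple[LabeledDataset, LabeledDataset]:
    """Remove sequences present in both label sets from each side."""
    shared = set(pos.sequences) & set(neg.sequences)
    keep_p = [i for i, p in enumerate(pos.peptides) if p.sequence not in shared]
    keep_n = [i for i, p in enumerate(neg.peptides) if p.sequence not in shared]
    return pos.subset(keep_p), neg.subset(keep_n)


def curate(ds: LabeledDataset, max_len: int = 50,
           identity_threshold: float = 0.80
           ) -> tuple[LabeledDataset, CurationReport]:
    """Full curation pipeline: length -> natural residues -> redundancy."""
    report = CurationReport(n_input=len(ds))
    ds = length_filter(ds, max_len, report)
    ds = natural_filter(ds, report)
    ds = greedy_redundancy_filter(ds, identity_threshold, report)
    return ds, report


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def make_imbalanced_split(pos: LabeledDataset, neg_pool: LabeledDataset,
                          ratio: int, seed: int) -> LabeledDataset:
    """Positives plus exactly ``ratio`` negatives per positive.

    Negatives are drawn uniformly without replacement from ``neg_pool`` with a
    generator seeded by ``seed``; the result is deterministic.
    """
    n_needed = ratio * len(pos)
    if len(neg_pool) < n_needed:
        raise ValueError(
            f"negative pool too small: need {n_needed}, have {len(neg_pool)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(neg_pool), size=n_needed, replace=False)
    neg = neg_pool.subset(sorted(chosen.tolist()))
    return LabeledDataset(
        peptides=list(pos.peptides) + list(neg.peptides),
        labels=[POSITIVE] * len(pos) + [NEGATIVE] * len(neg),
    )


def kfold_split(ds: LabeledDataset, k: int = 10, seed: int = 0) -> list[str]:
    """Stratified k-fold tags ``fold-0`` .. ``fold-{k-1}``, one per peptide."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ds) < k:
        raise ValueError(f"k={k} exceeds dataset size {len(ds)}")
    if any(y is None for y in ds.labels):
        raise ValueError("kfold_split requires labels")
    labels = np.asarray(ds.labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tags = [""] * len(ds)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(ds)), labels)):
        for i in test_idx:
            tags[i] = f"fold-{fold}"
    return tags
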