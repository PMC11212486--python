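"""Morgan (ECFP-style) circular fingerprints of peptide molecules.

The fingerprint labels every atom with an initial connectivity invariant and
then iteratively re-hashes each label together with the sorted
(bond-type, neighbour-label) pairs out to a fixed radius; every label emitted
along the way is folded modulo ``n_bits`` into a binary bit vector.  Radius 2
with 1024 bits (ECFP4/1024) is the configuration used for the local-structure
branch of the classifier.

The update-and-fold procedure here reproduces RDKit's MorganGenerator
bit-for-bit: the same 32-bit ``hash_combine`` mixing, 0-based layer seeding,
neighbour-pair ordering, and duplicate-environment suppression (an atom whose
grown bond environment coincides with one already emitted contributes no new
label and stops growing).  RDKit is used only to build the molecule and to
compute the initial atom invariants; the iterative hashing is done here, and
the test suite checks exact bit agreement against RDKit as an independent
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .data_io import Peptide, validate_natural

_M32 = 0xFFFFFFFF


def _hash_combine(seed: int, value: int) -> int:
    """Classic boost ``hash_combine`` on 32-bit unsigned integers."""
    return (seed ^ ((value + 0x9E3779B9 + ((seed << 6) & _M32)
                     + (seed >> 2)) & _M32)) & _M32


def _hash_pair(a: int, b: int) -> int:
    return _hash_combine(_hash_combine(0, a), b)


def peptide_to_molecule(p: Peptide | str) -> Chem.Mol:
    """Linear polypeptide molecule, N- to C-terminus, free neutral termini.

    Residues must be the 20 proteinogenic amino acids; no modifications,
    cyclisation or non-standard protonation are modelled.
    """
    seq = p.sequence if isinstance(p, Peptide) else p
    if not validate_natural(seq):
        raise ValueError(f"sequence contains non-natural residues: {seq!r}")
    mol = Chem.MolFromSequence(seq)
    if mol is None:  # pragma: no cover - guarded by validate_natural
        raise ValueError(f"could not build molecule for {seq!r}")
    return mol


@dataclass(frozen=True)
class Fingerprint1024:
    """Binary Morgan fingerprint folded to a fixed length (default 1024)."""

    bits: np.ndarray

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ValueError("bits must be a 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return self.bits.shape[0]

    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_bitstring(self) -> str:
        return "".join(map(str, self.bits.tolist()))


def morgan_environment_labels(mol: Chem.Mol, radius: int = 2
                              ) -> list[tuple[int, int, int]]:
    """All emitted (label, atom_index, layer) triples up to ``radius``.

    Layer 0 labels are the initial connectivity invariants; deeper layers
    re-hash the centre label with its sorted neighbour (bond, label) pairs.
    Environments whose bond set duplicates an already-emitted environment are
    suppressed and their centre atom stops growing, matching the canonical
    ECFP duplicate-removal rule.
    """
    n_atoms = mol.GetNumAtoms()
    invariants = list(rdMolDescriptors.GetConnectivityInvariants(mol))
    bond_invariants = [int(b.GetBondType()) for b in mol.GetBonds()]
    emitted = [(invariants[a], a, 0) for a in range(n_atoms)]
    seen_envs: list[int] = []       # bond-set masks already emitted
    atom_env = [0] * n_atoms        # per-atom grown bond-set mask
    dead = [False] * n_atoms
    for layer in range(radius):
        next_inv = list(invariants)
        next_env = list(atom_env)
        this_round: list[tuple[int, int, int]] = []
        for a in range(n_atoms):
            if dead[a]:
                continue
            atom = mol.GetAtomWithIdx(a)
            if atom.GetDegree() == 0:
                continue
            mask = atom_env[a]
            pairs = []
            for bond in atom.GetBonds():
                other = bond.GetOtherAtomIdx(a)
                mask |= (1 << bond.GetIdx()) | atom_env[other]
                pairs.append((bond_invariants[bond.GetIdx()], invariants[other]))
            pairs.sort()
            label = _hash_combine(layer, invariants[a])
            for b_inv, n_inv in pairs:
                label = _hash_combine(label, _hash_pair(b_inv, n_inv))
            next_inv[a] = label
            next_env[a] = mask
            this_round.append((mask, label, a))
        this_round.sort()
        for mask, label, a in this_round:
            if mask not in seen_envs:
                seen_envs.append(mask)
                emitted.append((label, a, layer + 1))
            else:
                dead[a] = True
        invariants = next_inv
        atom_env = next_env
    return emitted


def morgan_fingerprint(mol: Chem.Mol, radius: int = 2,
                       n_bits: int = 1024) -> Fingerprint1024:
    """Binary circular fingerprint: emitted labels folded modulo ``n_bits``."""
    bits = np.zeros(n_bits, dtype=np.uint8)
    for label, _atom, _layer in morgan_environment_labels(mol, radius):
        bits[label % n_bits] = 1
    return Fingerprint1024(bits)


def fingerprint_sequence(sequence: Peptide | str, radius: int = 2,
                         n_bits: int = 1024) -> Fingerprint1024:
    """Convenience: sequence -> molecule -> fingerprint."""
    return morgan_fingerprint(peptide_to_molecule(sequence), radius, n_bits)
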