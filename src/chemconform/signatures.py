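"""The Signatures circular molecular descriptor.

A signature of height *h* rooted at an atom is the canonical string of the
breadth-limited tree expansion from that atom: at each node all neighbours
except the one the node was reached from become children (rings therefore
re-appear at deeper levels up to the height bound; there are no
ring-closure markers). Atom tokens are ``[`` + element symbol + charge
suffix + ``]``; child renderings carry a bond prefix ("" single, ``=``
double, ``#`` triple, ``p`` aromatic) and are sorted lexicographically, so
the string is invariant to the input atom order. Heavy atoms only:
hydrogens never appear. A height-1 signature of an aromatic benzene carbon
is ``[C](p[C]p[C])``.

Feature values are occurrence counts over all (atom, height) pairs in the
configured height range; the per-record occurrence backmap supports
mapping feature contributions back to atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from rdkit import Chem

from .data import ChemDataset, MoleculeRecord, SparseFeatureMatrix

_BOND_TOKEN = {
    Chem.BondType.SINGLE: "",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: "p",
}


def _atom_token(atom: Chem.Atom) -> str:
    charge = atom.GetFormalCharge()
    suffix = ("+" * charge) if charge > 0 else ("-" * -charge)
    return f"[{atom.GetSymbol()}{suffix}]"


def atom_signature(mol: Chem.Mol, root: int, height: int) -> str:
    """Canonical signature string of the height-limited expansion from ``root``."""
    if root < 0 or root >= mol.GetNumAtoms():
        raise ValueError(f"invalid atom index {root}")
    if height < 0:
        raise ValueError("height must be non-negative")
    return _render(mol, mol.GetAtomWithIdx(root), parent_idx=-1, depth=0, height=height)


def _render(mol: Chem.Mol, atom: Chem.Atom, parent_idx: int, depth: int, height: int) -> str:
    token = _atom_token(atom)
    if depth >= height:
        return token
    children = []
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        if nbr.GetIdx() == parent_idx:
            continue
        sub = _render(mol, nbr, atom.GetIdx(), depth + 1, height)
        children.append(_BOND_TOKEN[bond.GetBondType()] + sub)
    if not children:
        return token
    children.sort()
    return token + "(" + "".join(children) + ")"


def _signature_atoms(mol: Chem.Mol, root: int, height: int) -> set[int]:
    """Atom indices visited by the expansion (BFS to the height bound)."""
    visited = {root}
    frontier = [(root, -1)]
    for _ in range(height):
        nxt = []
        for idx, parent in frontier:
            atom = mol.GetAtomWithIdx(idx)
            for nbr in atom.GetNeighbors():
                j = nbr.GetIdx()
                if j == parent:
                    continue
                visited.add(j)
                nxt.append((j, idx))
        frontier = nxt
    return visited


@dataclass
class SignatureVocabulary:
    """Signature string -> 1-based feature index, first-encounter order.

    Frozen at prediction time: unknown signatures are dropped (their
    per-molecule count is reported for diagnostics), never appended.
    """

    h_min: int = 1
    h_max: int = 3
    index: dict[str, int] = field(default_factory=dict)
    extra_columns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.index)

    @property
    def n_features(self) -> int:
        return len(self.index) + len(self.extra_columns)

    def add(self, text: str) -> int:
        idx = self.index.get(text)
        if idx is None:
            idx = len(self.index) + 1
            self.index[text] = idx
        return idx

    def signature_of_index(self, idx: int) -> str:
        for text, i in self.index.items():
            if i == idx:
                return text
        raise KeyError(idx)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            for text, idx in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{idx}\t{text}\n")

    @classmethod
    def load(cls, path: str, h_min: int = 1, h_max: int = 3) -> "SignatureVocabulary":
        vocab = cls(h_min=h_min, h_max=h_max)
        with open(path) as fh:
            for line in fh:
                idx_s, _, text = line.rstrip("\n").partition("\t")
                vocab.index[text] = int(idx_s)
        return vocab


# per record: feature index -> [(root atom, atoms reached), ...]
AtomFeatureMap = dict[int, list[tuple[int, frozenset[int]]]]


def record_signatures(mol: Chem.Mol, h_min: int, h_max: int):
    """Yield (signature string, root atom, height) for every (atom, height)."""
    for atom_idx in range(mol.GetNumAtoms()):
        for h in range(h_min, h_max + 1):
            yield atom_signature(mol, atom_idx, h), atom_idx, h


def map_occurrences(
    record: MoleculeRecord,
    vocabulary: SignatureVocabulary,
    h_min: int | None = None,
    h_max: int | None = None,
) -> AtomFeatureMap:
    """Occurrence backmap for one record under a frozen vocabulary.

    One occurrence per matching (root atom, height); the occurrence set is
    the set of atoms the expansion visits.
    """
    h_min = vocabulary.h_min if h_min is None else h_min
    h_max = vocabulary.h_max if h_max is None else h_max
    out: AtomFeatureMap = {}
    for text, root, h in record_signatures(record.structure, h_min, h_max):
        idx = vocabulary.index.get(text)
        if idx is None:
            continue
        out.setdefault(idx, []).append((root, frozenset(_signature_atoms(record.structure, root, h))))
    return out


def featurize(
    dataset: ChemDataset,
    h_min: int = 1,
    h_max: int = 3,
    vocabulary: SignatureVocabulary | None = None,
) -> tuple[SignatureVocabulary, SparseFeatureMatrix, list[AtomFeatureMap]]:
    """Compute signature count vectors for a dataset.

    Training mode (no vocabulary) builds the vocabulary in first-encounter
    order; prediction mode uses the frozen vocabulary and drops unseen
    signatures. External descriptors, if attached, are appended after the
    signature features in declared column order.
    """
    if not 0 <= h_min <= h_max:
        raise ValueError("need 0 <= h_min <= h_max")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    training = vocabulary is None
    if training:
        vocabulary = SignatureVocabulary(h_min=h_min, h_max=h_max)
        if dataset.records and dataset.records[0].extra_features:
            vocabulary.extra_columns = list(dataset.records[0].extra_features)
    n_sig = None if training else len(vocabulary)

    rows, cols, vals = [], [], []
    backmaps: list[AtomFeatureMap] = []
    dropped_counts = []
    for i, rec in enumerate(dataset.records):
        counts: dict[int, int] = {}
        backmap: AtomFeatureMap = {}
        dropped = 0
        for text, root, h in record_signatures(rec.structure, vocabulary.h_min, vocabulary.h_max):
            if training:
                idx = vocabulary.add(text)
            else:
                idx = vocabulary.index.get(text)
                if idx is None:
                    dropped += 1
                    continue
            counts[idx] = counts.get(idx, 0) + 1
            backmap.setdefault(idx, []).append(
                (root, frozenset(_signature_atoms(rec.structure, root, h)))
            )
        for idx, c in counts.items():
            rows.append(i)
            cols.append(idx - 1)
            vals.append(float(c))
        backmaps.append(backmap)
        dropped_counts.append(dropped)

    n_sig = len(vocabulary)
    n_extra = len(vocabulary.extra_columns)
    for i, rec in enumerate(dataset.records):
        for j, col in enumerate(vocabulary.extra_columns):
            v = rec.extra_features.get(col, 0.0)
            if v != 0.0:
                rows.append(i)
                cols.append(n_sig + j)
                vals.append(float(v))

    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(dataset), n_sig + n_extra)
    )
    matrix = SparseFeatureMatrix(X, dataset.labels)
    matrix.dropped_signatures = np.asarray(dropped_counts)  # type: ignore[attr-defined]
    return vocabulary, matrix, backmaps


class SignatureFeaturizer:
    """Transformer-style wrapper: ``fit`` builds the vocabulary, ``transform``
    featurizes under it (unknown signatures dropped)."""

    def __init__(self, h_min: int = 1, h_max: int = 3):
        self.h_min = h_min
        self.h_max = h_max

    def get_params(self, deep: bool = True) -> dict:
        return {"h_min": self.h_min, "h_max": self.h_max}

    def set_params(self, **params) -> "SignatureFeaturizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, dataset: ChemDataset) -> "SignatureFeaturizer":
        self.vocabulary_, self.matrix_, self.backmaps_ = featurize(
            dataset, self.h_min, self.h_max
        )
        return self

    def fit_transform(self, dataset: ChemDataset) -> SparseFeatureMatrix:
        self.fit(dataset)
        return self.matrix_

    def transform(self, dataset: ChemDataset) -> SparseFeatureMatrix:
        _, matrix, _ = featurize(dataset, vocabulary=self.vocabulary_)
        return matrix
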