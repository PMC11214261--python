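"""Chemical and numeric dataset handling.

Reads CSV (SMILES column + label column) and SDF inputs into
:class:`ChemDataset`, attaches externally computed descriptor columns,
produces proper-train / calibration splits for inductive conformal
calibration, and persists sparse feature matrices in a LIBSVM-style text
dialect (``label idx:value idx:value ...`` with 1-based ascending indices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from rdkit import Chem
from rdkit import RDLogger
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class DatasetError(ValueError):
    """Raised for malformed or unusable dataset inputs."""


def parse_structure(text: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule with aromaticity perceived.

    Implicit hydrogens are kept implicit; only heavy atoms appear in the
    graph. Raises :class:`StructureParseError` for unparseable input.
    """
    if not text or not text.strip():
        raise StructureParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {text!r}")
    return mol


@dataclass
class MoleculeRecord:
    """One observation: a molecule, its label and optional extra descriptors."""

    id: str
    structure: Chem.Mol
    label: object = None  # float for regression, str for classification
    extra_features: dict[str, float] = field(default_factory=dict)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.structure)


@dataclass
class ChemDataset:
    """Ordered molecule records sharing one task.

    ``label_domain`` lists classification labels in first-appearance order;
    all outputs report these labels, never internal indices.
    """

    records: list[MoleculeRecord]
    task: str  # "classification" | "regression"
    label_domain: list[str] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise DatasetError(f"unknown task {self.task!r}")
        if self.task == "classification" and not self.label_domain:
            seen: list[str] = []
            for r in self.records:
                if r.label is not None and r.label not in seen:
                    seen.append(r.label)
            self.label_domain = seen

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([r.label for r in self.records])

    def warn_duplicates(self) -> list[str]:
        """Return canonical SMILES occurring more than once (kept as records)."""
        counts: dict[str, int] = {}
        for r in self.records:
            s = r.smiles
            counts[s] = counts.get(s, 0) + 1
        dups = [s for s, c in counts.items() if c > 1]
        if dups:
            logger.warning("dataset contains %d duplicate structures", len(dups))
        return dups


def read_dataset(
    path: str,
    fmt: str = "csv",
    smiles_column: str = "smiles",
    label_column: str = "label",
    task: str = "classification",
    delimiter: str = ",",
    id_column: str | None = None,
) -> ChemDataset:
    """Read a CSV (SMILES + label columns) or SDF (label as named property).

    Rows with unparseable structures are skipped and counted, not fatal.
    """
    records: list[MoleculeRecord] = []
    n_skipped = 0
    if fmt == "csv":
        df = pd.read_csv(path, delimiter=delimiter)
        for col in (smiles_column, label_column):
            if col not in df.columns:
                raise DatasetError(f"column {col!r} not found in {path}")
        for i, row in df.iterrows():
            rid = str(row[id_column]) if id_column else f"row{i}"
            try:
                mol = parse_structure(str(row[smiles_column]))
            except StructureParseError:
                n_skipped += 1
                continue
            records.append(MoleculeRecord(rid, mol, _coerce_label(row[label_column], task)))
    elif fmt == "sdf":
        suppl = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(suppl):
            if mol is None:
                n_skipped += 1
                continue
            if not mol.HasProp(label_column):
                raise DatasetError(f"SDF entry {i} lacks property {label_column!r}")
            rid = mol.GetProp("_Name") or f"mol{i}"
            records.append(MoleculeRecord(rid, mol, _coerce_label(mol.GetProp(label_column), task)))
    else:
        raise DatasetError(f"unknown format {fmt!r}")
    if not records:
        raise DatasetError(f"no valid records in {path}")
    if n_skipped:
        logger.info("skipped %d invalid structures in %s", n_skipped, path)
    return ChemDataset(records, task, n_skipped=n_skipped)


def _coerce_label(value, task: str):
    if task == "regression":
        return float(value)
    return str(value)


def attach_external_descriptors(
    dataset: ChemDataset,
    table: pd.DataFrame,
    policy: str = "strict",
) -> ChemDataset:
    """Attach per-id numeric descriptor columns to each record.

    ``table`` is indexed by record id. Downstream featurization appends
    these after signature features in declared column order. With
    ``policy='drop-missing'`` records absent from the table are dropped;
    the default is an error.
    """
    if table.shape[1] == 0:
        return dataset
    kept: list[MoleculeRecord] = []
    for rec in dataset.records:
        if rec.id not in table.index:
            if policy == "drop-missing":
                continue
            raise DatasetError(f"record id {rec.id!r} missing from descriptor table")
        row = table.loc[rec.id]
        feats = {}
        for col in table.columns:
            v = row[col]
            try:
                feats[col] = float(v)
            except (TypeError, ValueError) as exc:
                raise DatasetError(
                    f"non-numeric descriptor value {v!r} at id={rec.id!r}, column={col!r}"
                ) from exc
        rec.extra_features = feats
        kept.append(rec)
    return ChemDataset(kept, dataset.task, dataset.label_domain, dataset.n_skipped)


@dataclass
class SamplingStrategy:
    """How training data is split into proper-train and calibration parts.

    ``kind='random'`` / ``'random-stratified'`` draw ``n_splits`` independent
    splits holding out ``calibration_ratio`` of the data (one split = ICP,
    several = ACP); ``kind='fold'`` produces ``n_splits`` folded splits whose
    calibration parts partition the data (CCP); ``kind='predefined'`` carries
    explicit index partitions.
    """

    kind: str = "random"
    calibration_ratio: float = 0.2
    n_splits: int = 1
    seed: int = 0
    predefined: list[tuple[Sequence[int], Sequence[int]]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("random", "random-stratified", "predefined", "fold"):
            raise DatasetError(f"unknown sampling kind {self.kind!r}")
        if self.kind in ("random", "random-stratified") and not 0 < self.calibration_ratio < 1:
            raise DatasetError("calibration_ratio must be in (0, 1)")
        if self.n_splits < 1:
            raise DatasetError("n_splits must be positive")


def split_sampling(
    n: int,
    strategy: SamplingStrategy,
    labels: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return ``[(proper_train_idx, calibration_idx), ...]`` per split.

    Reproducible from the strategy seed; fold-kind calibration parts are
    disjoint and exhaustive.
    """
    if n < 2:
        raise DatasetError("need at least 2 records to split")
    if strategy.kind == "predefined":
        if not strategy.predefined:
            raise DatasetError("predefined strategy lacks partitions")
        return [
            (np.asarray(tr, dtype=int), np.asarray(ca, dtype=int))
            for tr, ca in strategy.predefined
        ]
    if strategy.kind == "fold":
        if strategy.n_splits > n:
            raise DatasetError("more folds than records")
        if labels is not None and len(np.unique(labels)) > 1 and _stratifiable(labels, strategy.n_splits):
            kf = StratifiedKFold(n_splits=strategy.n_splits, shuffle=True, random_state=strategy.seed)
            return [(tr, ca) for tr, ca in kf.split(np.zeros(n), labels)]
        kf = KFold(n_splits=strategy.n_splits, shuffle=True, random_state=strategy.seed)
        return [(tr, ca) for tr, ca in kf.split(np.zeros(n))]

    n_cal = int(round(n * strategy.calibration_ratio))
    n_cal = min(max(n_cal, 1), n - 1)
    rng = np.random.default_rng(strategy.seed)
    splits = []
    for _ in range(strategy.n_splits):
        if strategy.kind == "random-stratified":
            if labels is None:
                raise DatasetError("stratified sampling requires labels")
            cal_idx = _stratified_holdout(labels, n_cal, rng)
        else:
            cal_idx = np.sort(rng.choice(n, size=n_cal, replace=False))
        mask = np.ones(n, dtype=bool)
        mask[cal_idx] = False
        splits.append((np.flatnonzero(mask), cal_idx))
    return splits


def _stratifiable(labels: np.ndarray, k: int) -> bool:
    _, counts = np.unique(labels, return_counts=True)
    return counts.min() >= k


def _stratified_holdout(labels: np.ndarray, n_cal: int, rng) -> np.ndarray:
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    # proportional allocation, largest-remainder rounding
    exact = counts * n_cal / n
    alloc = np.floor(exact).astype(int)
    rem = n_cal - alloc.sum()
    order = np.argsort(-(exact - alloc))
    alloc[order[:rem]] += 1
    if np.any(alloc < 1) or np.any(alloc >= counts):
        raise DatasetError("stratification impossible: a class is too small")
    picks = []
    for cls, k in zip(classes, alloc):
        members = np.flatnonzero(labels == cls)
        picks.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(picks))


@dataclass
class SparseFeatureMatrix:
    """Sparse per-record count vectors with an aligned label column.

    ``X`` is a CSR matrix; feature indices are 1-based in the persisted
    text dialect and 0-based in ``X`` columns.
    """

    X: sp.csr_matrix
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.y):
            raise DatasetError("row count does not match label count")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return self.X.shape[0]


def write_sparse(matrix: SparseFeatureMatrix, path: str) -> None:
    """Write ``label idx:value ...`` rows, 1-based ascending indices."""
    X = matrix.X.tocsr()
    with open(path, "w") as fh:
        for i in range(X.shape[0]):
            start, end = X.indptr[i], X.indptr[i + 1]
            cols = X.indices[start:end]
            vals = X.data[start:end]
            order = np.argsort(cols)
            parts = [_fmt_number(matrix.y[i])]
            parts += [f"{cols[j] + 1}:{_fmt_number(vals[j])}" for j in order]
            fh.write(" ".join(parts) + "\n")


def _fmt_number(v) -> str:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return str(v)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def read_sparse(path: str, n_features: int | None = None, numeric_labels: bool = True) -> SparseFeatureMatrix:
    """Read the sparse text dialect written by :func:`write_sparse`."""
    labels: list = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    max_col = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            labels.append(float(parts[0]) if numeric_labels else parts[0])
            prev = 0
            for tok in parts[1:]:
                idx_s, _, val_s = tok.partition(":")
                idx = int(idx_s)
                if idx <= prev:
                    raise DatasetError(
                        f"{path}:{lineno}: feature indices not strictly ascending"
                    )
                prev = idx
                rows.append(len(labels) - 1)
                cols.append(idx - 1)
                vals.append(float(val_s))
                max_col = max(max_col, idx)
    n_feat = n_features if n_features is not None else max_col
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(labels), n_feat)
    )
    return SparseFeatureMatrix(X, np.asarray(labels))
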