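"""Deterministic synthetic data: numeric sets with known statistical
structure and toy molecule sets with a planted structure-activity rule.

The numeric generators produce exchangeable samples (i.i.d. draws), which
is exactly the assumption conformal validity rests on, so they are
legitimate inputs for the validity test suites. The molecular generator
assembles valence-valid SMILES from a fixed fragment list; classification
labels encode presence of a planted substructure (a nitro group by
default) and regression labels the aromatic-atom count plus Gaussian
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import ChemDataset, MoleculeRecord, SparseFeatureMatrix, parse_structure


@dataclass
class SyntheticSpec:
    """Fully determines a generated sample given its seed."""

    task: str = "classification"
    n: int = 1000
    n_features: int = 5
    class_separation: float = 1.0  # class means at +/- separation on axis 0
    imbalance: float = 0.5  # fraction in class "A"
    weights: np.ndarray | None = None  # regression
    noise: float = 1.0
    heteroscedastic: bool = False
    seed: int = 0


def gen_numeric_classification(spec: SyntheticSpec) -> SparseFeatureMatrix:
    """Two-class Gaussian mixture with unit covariance.

    Class "A" has mean +separation and class "B" mean -separation on the
    first axis; the class allocation is exact (``round(n * imbalance)``
    rows of "A"). With separation 1 the Bayes error is Phi(-1) ~ 0.159.
    """
    rng = np.random.default_rng(spec.seed)
    n_a = int(round(spec.n * spec.imbalance))
    n_b = spec.n - n_a
    if min(n_a, n_b) < 1:
        raise ValueError("imbalance leaves a class empty")
    X = rng.standard_normal((spec.n, spec.n_features))
    y = np.array(["A"] * n_a + ["B"] * n_b)
    X[:n_a, 0] += spec.class_separation
    X[n_a:, 0] -= spec.class_separation
    perm = rng.permutation(spec.n)
    return SparseFeatureMatrix(sp.csr_matrix(X[perm]), y[perm])


def gen_numeric_regression(spec: SyntheticSpec) -> SparseFeatureMatrix:
    """Linear model y = w.x + noise * scale(x).

    Homoscedastic scale is 1; the heteroscedastic option uses
    scale(x) = 1 + |x_1| so interval normalization has signal to exploit.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.weights
    if w is None:
        w = np.zeros(spec.n_features)
        w[: min(3, spec.n_features)] = [2.0, -1.0, 0.5][: min(3, spec.n_features)]
    w = np.asarray(w, dtype=float)
    X = rng.standard_normal((spec.n, spec.n_features))
    scale = 1.0 + np.abs(X[:, 0]) if spec.heteroscedastic else np.ones(spec.n)
    y = X @ w + spec.noise * scale * rng.standard_normal(spec.n)
    return SparseFeatureMatrix(sp.csr_matrix(X), y)


# fragments whose SMILES concatenate into valid molecules: every fragment
# starts with an atom that tolerates one extra single bond, and ring
# closure digits are renumbered per position to avoid collisions. Linker
# fragments also END in an atom with a free valence; terminal fragments
# (halogenated/unsaturated ends) may only close a molecule.
_LINKERS = [
    "C", "CC", "CCC", "C(C)C", "CO", "CCO", "CN", "CCN", "C=C", "CC=C",
    "C(=O)C", "C(=O)O", "C(=O)N", "COC", "CSC", "CS", "CC(C)C", "CCCC",
    "c1ccccc1", "c1ccc(C)cc1", "c1ccncc1", "c1occc1", "c1sccc1",
    "c1ccc2ccccc2c1",
]
_TERMINALS = ["CF", "CCl", "CBr", "C(F)(F)F", "C#N", "CC#N"]
NITRO_FRAGMENT = "[N+](=O)[O-]"


def _renumber_rings(smiles: str, offset: int) -> str:
    out = []
    for ch in smiles:
        if ch.isdigit():
            n = int(ch) + offset
            out.append(str(n) if n <= 9 else f"%{n}")
        else:
            out.append(ch)
    return out


def assemble_smiles(fragments: list[str]) -> str:
    """Concatenate fragment SMILES with per-fragment ring renumbering."""
    parts = []
    offset = 0
    for frag in fragments:
        parts.extend(_renumber_rings(frag, offset))
        offset += 2
    return "".join(parts)


def gen_toy_molecules(
    n: int,
    rule: str = "substructure-presence",
    noise: float = 0.0,
    seed: int = 0,
    n_fragments: tuple[int, int] = (2, 4),
) -> ChemDataset:
    """Toy molecules with a planted structure-activity rule.

    ``rule='substructure-presence'``: binary labels "active"/"inactive"
    encoding the presence of a nitro group, planted in half the molecules;
    ``noise`` is the label-flip probability. ``rule='aromatic-count'``:
    regression labels = aromatic-atom count + Gaussian(0, noise).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    task = "classification" if rule == "substructure-presence" else "regression"
    for i in range(n):
        k = rng.integers(n_fragments[0], n_fragments[1] + 1)
        frags = [_LINKERS[j] for j in rng.integers(0, len(_LINKERS), size=k)]
        has_planted = False
        if rule == "substructure-presence" and rng.uniform() < 0.5:
            # the nitro oxygen cannot carry a further bond, so plant terminally
            frags.append(NITRO_FRAGMENT)
            has_planted = True
        elif rng.uniform() < 0.3:
            frags.append(_TERMINALS[rng.integers(0, len(_TERMINALS))])
        mol = parse_structure(assemble_smiles(frags))
        if rule == "substructure-presence":
            label = "active" if has_planted else "inactive"
            if noise > 0 and rng.uniform() < noise:
                label = "inactive" if label == "active" else "active"
        else:
            aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
            label = float(aromatic) + (noise * rng.standard_normal() if noise > 0 else 0.0)
        records.append(MoleculeRecord(f"toy{i}", mol, label))
    domain = ["active", "inactive"] if task == "classification" else []
    return ChemDataset(records, task, label_domain=domain if task == "classification" else [])
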