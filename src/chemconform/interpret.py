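"""Atom-level interpretation of predictions.

A feature's contribution is the removal finite difference: the change in
the model's raw output (regression midpoint, or decision score of the
predicted class) when that feature's count is zeroed. For a linear scorer
this is exactly weight * value. Contributions are mapped back to atoms by
attributing each feature to the root atoms of its signature occurrences,
dividing the feature contribution equally among occurrences; the
"significant signature" is the present feature with the largest
contribution, reported together with the atom sets its occurrences cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .conformal import ConformalClassifier, ConformalRegressor
from .signatures import AtomFeatureMap, SignatureVocabulary


@dataclass
class AtomContributionMap:
    """Per-atom contributions with normalization and the top signature.

    ``normalized`` divides by the maximum absolute contribution (all-zero
    maps stay zero); positive values push the prediction toward the
    predicted class / larger predicted values.
    """

    contributions: dict[int, float]
    normalized: dict[int, float]
    significant_signature: str | None
    significant_atoms: list[set[int]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "atoms": {
                str(a): {"raw": self.contributions[a], "normalized": self.normalized[a]}
                for a in sorted(self.contributions)
            },
            "significant_signature": self.significant_signature,
            "significant_atoms": [sorted(s) for s in self.significant_atoms],
        }


def _model_score(model, X) -> np.ndarray:
    """Raw scalar output used for attribution, averaged over splits."""
    if isinstance(model, ConformalRegressor):
        return model.predict(X)
    p = model.predict_p(X)
    j = int(np.argmax(p[0]))
    scores = []
    for scorer, _ in model.models_:
        d = scorer.decision(X)
        col = list(scorer.classes).index(model.classes_[j])
        scores.append(d[:, col])
    return np.mean(scores, axis=0)


def feature_contributions(model, row) -> dict[int, float]:
    """Removal-based contribution per nonzero feature (0-based indices).

    contribution(f) = s(x) - s(x with feature f zeroed); zero-valued
    features contribute 0 and are omitted.
    """
    dense_input = not sp.issparse(row)
    row = sp.csr_matrix(row)
    if row.shape[0] != 1:
        raise ValueError("expected a single feature row")
    nz = row.indices
    if len(nz) == 0:
        return {}
    # batch: first row is x itself, then one row per zeroed feature
    rows = [row]
    for f in nz:
        r = row.copy().tolil()
        r[0, f] = 0.0
        rows.append(r.tocsr())
    X = sp.vstack(rows).tocsr()
    if dense_input:
        X = X.toarray()
    s = _model_score(model, X)
    base = s[0]
    return {int(f): float(base - s[1 + i]) for i, f in enumerate(nz)}


def atom_gradient(
    model,
    row,
    backmap: AtomFeatureMap,
    n_atoms: int,
    vocabulary: SignatureVocabulary | None = None,
    spread: bool = False,
) -> AtomContributionMap:
    """Aggregate feature contributions onto atoms.

    Each occurrence of a feature receives an equal share of the feature's
    contribution, credited to its root atom (or, with ``spread=True``,
    divided over the occurrence's atom set). The significant signature is
    the argmax-contribution feature present in the molecule; ties go to
    the lexicographically smallest signature string.
    """
    contribs = feature_contributions(model, row)
    atom_vals = {a: 0.0 for a in range(n_atoms)}
    best: tuple[float, str, int] | None = None
    for fidx_1based, occurrences in backmap.items():
        f0 = fidx_1based - 1
        c = contribs.get(f0, 0.0)
        share = c / len(occurrences)
        for root, atoms in occurrences:
            if spread:
                for a in atoms:
                    atom_vals[a] += share / len(atoms)
            else:
                atom_vals[root] += share
        if occurrences:
            text = (
                vocabulary.signature_of_index(fidx_1based)
                if vocabulary is not None
                else str(fidx_1based)
            )
            key = (-c, text)
            if best is None or key < (-best[0], best[1]):
                best = (c, text, fidx_1based)
    max_abs = max((abs(v) for v in atom_vals.values()), default=0.0)
    normalized = {
        a: (v / max_abs if max_abs > 0 else 0.0) for a, v in atom_vals.items()
    }
    sig_text = best[1] if best is not None else None
    sig_atoms = (
        [set(atoms) for _, atoms in backmap[best[2]]] if best is not None else []
    )
    return AtomContributionMap(atom_vals, normalized, sig_text, sig_atoms)
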