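# chemconform

Confidence-calibrated QSAR modeling: mondrian conformal prediction and
Venn-ABERS probabilistic calibration on top of the Signatures circular
molecular descriptor, with conformal-aware evaluation, grid-search tuning,
atom-level interpretation of predictions, and a command-line workflow.

## The problem

Point predictions from QSAR models come with no per-compound confidence.
Conformal prediction turns any scoring model into a predictor with a
finite-sample guarantee: under exchangeability of calibration and test
data, the error rate is at most a user-chosen significance level ε.

For classification, the training set is split into a *proper training*
set (fits the underlying scorer — sparse linear/RBF SVM or logistic
regression) and a *calibration* set. A nonconformity measure
α = h(x, y) scores how strange an observation is; the p-value of a test
object x for a candidate label y ranks its nonconformity against the
calibration list:

p_{n+1} = |{ j = 1..n+1 : α_j ≥ α_{n+1} }| / (n + 1)

Ranking is *mondrian* (class-conditional): α(x, y) is compared only
against calibration examples whose true label is y, which makes the
guarantee hold per class and copes with imbalance without balancing
tricks. The prediction set at significance ε is {y : p_y ≥ ε} — possibly
empty, single or multi-label. Smoothed and linearly interpolated p-value
variants refine the granularity of small calibration sets.

For regression the output is an interval ŷ ± α_(k)·σ(x) with
k = ⌈(1−ε)(n+1)⌉, where σ(x) is the difficulty scale of the chosen
nonconformity measure — 1 for `abs-diff`, or an error-model estimate plus
a smoothing factor β (default 0.01) for the `normalized` and
`log-normalized` kinds. One estimator covers ICP (one split), ACP
(several random splits) and CCP (folded splits) via the sampling
strategy; a transductive TCP classifier retrains per test object.
Venn-ABERS calibration produces probability pairs (p0, p1) via isotonic
regression with the test object tentatively labelled 0 and 1, merged as
p = p1 / (1 − p0 + p1) (geometric-mean merge across CVAP folds).

Molecules are represented by Signatures: canonical atom-rooted subgraph
strings up to a height bound (a benzene carbon at height 1 is
`[C](p[C]p[C])`), counted into sparse vectors, with an occurrence backmap
that lets feature contributions be attributed back to atoms.

## Worked example

```python
import numpy as np
from chemconform import ConformalClassifier, SamplingStrategy, featurize
from chemconform.synthetic import gen_toy_molecules

train = gen_toy_molecules(400, seed=0)           # planted nitro-group rule
test = gen_toy_molecules(5, seed=1)
vocab, mtrain, _ = featurize(train, h_min=1, h_max=2)
_, mtest, _ = featurize(test, vocabulary=vocab)  # frozen vocabulary

model = ConformalClassifier(
    sampling=SamplingStrategy(kind="random-stratified", calibration_ratio=0.2, seed=0),
    seed=0,
).fit(mtrain.X, np.asarray(train.labels))

p = model.predict_p(mtest.X)
sets = model.predict_set(mtest.X, epsilon=0.2)
for rec, pv, s in zip(test.records, p, sets):
    labels = ",".join(str(c) for c, inc in zip(model.classes_, s) if inc)
    print(f"{rec.id}: p_active={pv[0]:.3f} p_inactive={pv[1]:.3f} "
          f"set@0.2={{{labels}}} true={rec.label}")
```

prints

```
toy0: p_active=0.854 p_inactive=0.024 set@0.2={active} true=active
toy1: p_active=0.024 p_inactive=0.341 set@0.2={inactive} true=inactive
toy2: p_active=0.024 p_inactive=0.244 set@0.2={inactive} true=inactive
toy3: p_active=0.024 p_inactive=0.756 set@0.2={inactive} true=inactive
toy4: p_active=0.902 p_inactive=0.024 set@0.2={active} true=active
```

Each row carries one p-value per class; the prediction set keeps every
label with p ≥ 0.2. All five sets here are single-label and correct — at
ε = 0.2 the model is allowed to be wrong for at most ~20% of compounds,
and p-values near the 1/(n_cal+1) floor (0.024) mark labels the model
confidently excludes.

The same workflow is available from a shell:

```bash
chemconform precompute --input train.csv --task classification --out pre
chemconform train --precomputed pre --sampling random-stratified --out model.zip
chemconform predict --model model.zip --input new.csv --significance 0.2
```

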