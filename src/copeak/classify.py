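"""Bernoulli naive Bayes, L1 k-means baseline, ROC feature ranking and CV.

The classifier models each of the 67 binary features as an independent
Bernoulli variable per class. With only 18 validated positive training
peaks, maximum-likelihood Bernoulli parameters hit 0/1 and break the
product form, so parameters are add-one (Laplace) smoothed:

    theta[c][j] = (count of x_j = 1 in class c + 1) / (n_c + 2)

Posteriors are computed in log space and a peak is called positive when
P(positive | x) >= threshold (0.8 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class LabeledSet:
    """Feature vectors with {positive, negative} labels and ids."""

    X: np.ndarray            # (n, d) 0/1 matrix
    y: np.ndarray            # (n,) 1 = positive, 0 = negative
    ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not (self.X.shape[0] == self.y.shape[0] == len(self.ids)):
            raise ValueError("X, y and ids must have equal lengths")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("features must be binary")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def labels(self) -> list[str]:
        return [POSITIVE if v else NEGATIVE for v in self.y]


@dataclass
class NBModel:
    """Fitted Bernoulli naive Bayes parameters.

    ``theta_pos[j]``/``theta_neg[j]`` are the smoothed Bernoulli parameters
    P(x_j = 1 | class); both lie strictly inside (0, 1).
    """

    prior_pos: float
    prior_neg: float
    theta_pos: np.ndarray
    theta_neg: np.ndarray
    threshold: float = 0.8

    @property
    def n_features(self) -> int:
        return self.theta_pos.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "model": "bernoulli_naive_bayes",
            "feature_layout_version": 1,
            "prior_pos": self.prior_pos,
            "prior_neg": self.prior_neg,
            "theta_pos": self.theta_pos.tolist(),
            "theta_neg": self.theta_neg.tolist(),
            "threshold": self.threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NBModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(prior_pos=payload["prior_pos"],
                   prior_neg=payload["prior_neg"],
                   theta_pos=np.asarray(payload["theta_pos"]),
                   theta_neg=np.asarray(payload["theta_neg"]),
                   threshold=payload["threshold"])


def nb_fit(train: LabeledSet, threshold: float = 0.8) -> NBModel:
    """Fit class priors and add-one-smoothed Bernoulli parameters."""
    n_pos = int(train.y.sum())
    n_neg = len(train) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training set must contain both classes")
    Xpos = train.X[train.y == 1]
    Xneg = train.X[train.y == 0]
    theta_pos = (Xpos.sum(axis=0) + 1.0) / (n_pos + 2.0)
    theta_neg = (Xneg.sum(axis=0) + 1.0) / (n_neg + 2.0)
    n = n_pos + n_neg
    return NBModel(prior_pos=n_pos / n, prior_neg=n_neg / n,
                   theta_pos=theta_pos, theta_neg=theta_neg,
                   threshold=threshold)


def _log_joint(model: NBModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model "
            f"({model.n_features})")
    lp = np.log(model.prior_pos) + X @ np.log(model.theta_pos) \
        + (1.0 - X) @ np.log1p(-model.theta_pos)
    ln = np.log(model.prior_neg) + X @ np.log(model.theta_neg) \
        + (1.0 - X) @ np.log1p(-model.theta_neg)
    return lp, ln


def nb_posterior_matrix(model: NBModel, X: np.ndarray) -> np.ndarray:
    """P(positive | x) for each row of X, computed in log space."""
    lp, ln = _log_joint(model, X)
    return np.exp(lp - np.logaddexp(lp, ln))


def nb_posterior(model: NBModel, x: np.ndarray) -> float:
    """P(positive | x) for a single feature vector."""
    return float(nb_posterior_matrix(model, np.asarray(x).reshape(1, -1))[0])


def nb_classify(model: NBModel, x: np.ndarray) -> str:
    """Positive iff P(positive | x) >= model.threshold (inclusive)."""
    return POSITIVE if nb_posterior(model, x) >= model.threshold else NEGATIVE


def nb_classify_matrix(model: NBModel, X: np.ndarray) -> tuple[list[str], np.ndarray]:
    post = nb_posterior_matrix(model, X)
    labels = [POSITIVE if p >= model.threshold else NEGATIVE for p in post]
    return labels, post


def sample_training(pos_X: np.ndarray, pos_ids: list[str],
                    neg_X: np.ndarray, neg_ids: list[str],
                    ratio: int, seed: int) -> LabeledSet:
    """All positives plus ``ratio * n_pos`` negatives drawn without
    replacement (deterministic for a fixed seed)."""
    pos_X = np.asarray(pos_X)
    neg_X = np.asarray(neg_X)
    n_neg = ratio * pos_X.shape[0]
    if neg_X.shape[0] < n_neg:
        raise ValueError(
            f"negative pool of {neg_X.shape[0]} too small for "
            f"{n_neg} draws (ratio 1:{ratio})")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(neg_X.shape[0], size=n_neg, replace=False))
    X = np.vstack([pos_X, neg_X[chosen]])
    y = np.concatenate([np.ones(pos_X.shape[0], dtype=np.int8),
                        np.zeros(n_neg, dtype=np.int8)])
    ids = list(pos_ids) + [neg_ids[i] for i in chosen]
    return LabeledSet(X=X, y=y, ids=ids)


@dataclass
class ClusterResult:
    """k = 2 city-block k-means output; cluster 1 is the larger cluster."""

    assignment: np.ndarray      # (n,) values in {1, 2}
    centroids: np.ndarray       # (2, d) real-valued (component-wise medians)
    inertia: float              # total L1 distance to assigned centroids
    inertia_history: list[float] = field(default_factory=list)


def _l1_assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, float]:
    d = np.abs(X[:, None, :] - centroids[None, :, :]).sum(axis=2)
    assign = d.argmin(axis=1)          # ties -> lower cluster index
    return assign, float(d[np.arange(X.shape[0]), assign].sum())


def kmeans2(X: np.ndarray, seed: int = 0, restarts: int = 20,
            max_iter: int = 200) -> ClusterResult:
    """Lloyd-style k = 2 clustering under city-block (L1) distance.

    Centroids are component-wise medians (the L1 minimizer); each restart
    initializes from two distinct random rows; the best restart by final
    inertia wins. Assignment ties go to the lower cluster index.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2 or np.all(X == X[0]):
        raise ValueError("need at least two distinct rows")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(restarts):
        centroids = _init_distinct_rows(X, rng)
        assign = np.full(X.shape[0], -1)
        history: list[float] = []
        for _ in range(max_iter):
            new_assign, inertia = _l1_assign(X, centroids)
            history.append(inertia)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for k in (0, 1):
                members = X[assign == k]
                if members.shape[0] == 0:
                    # re-seed an emptied cluster at the farthest point
                    other = centroids[1 - k]
                    far = np.abs(X - other).sum(axis=1).argmax()
                    centroids[k] = X[far]
                else:
                    centroids[k] = np.median(members, axis=0)
        final_inertia = history[-1]
        if best is None or final_inertia < best[0]:
            best = (final_inertia, assign.copy(), centroids.copy(), history)
    inertia, assign, centroids, history = best
    # relabel so cluster 1 is the larger one
    sizes = [(assign == k).sum() for k in (0, 1)]
    order = (0, 1) if sizes[0] >= sizes[1] else (1, 0)
    relabeled = np.where(assign == order[0], 1, 2)
    return ClusterResult(assignment=relabeled,
                         centroids=centroids[list(order)],
                         inertia=inertia, inertia_history=history)


def _init_distinct_rows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    for _ in range(1000):
        i, j = rng.choice(X.shape[0], size=2, replace=False)
        if not np.array_equal(X[i], X[j]):
            return np.stack([X[i], X[j]]).astype(np.float64)
    raise ValueError("could not find two distinct rows to initialize")


def rank_features_roc(train: LabeledSet) -> list[tuple[int, float]]:
    """Rank features by ROC class-separability, |AUC_j - 0.5|.

    AUC uses the midrank (Mann-Whitney) convention for tied scores; the
    result is sorted by descending criterion, ties by ascending feature
    index. Criterion is in [0, 0.5]: 0.5 = perfect separation, 0 = none.
    """
    n_pos = int(train.y.sum())
    n_neg = len(train) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC ranking")
    scored = []
    for j in range(train.X.shape[1]):
        ranks = rankdata(train.X[:, j])
        auc = (ranks[train.y == 1].sum() - n_pos * (n_pos + 1) / 2) \
            / (n_pos * n_neg)
        scored.append((j, abs(auc - 0.5)))
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def _stratified_folds(y: np.ndarray, folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold index per example: each class shuffled then dealt round-robin."""
    fold_of = np.empty(y.shape[0], dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.shape[0] < folds:
            raise ValueError(
                f"class {cls} has {idx.shape[0]} examples, fewer than "
                f"{folds} folds")
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.shape[0]) % folds
    return fold_of


def confusion_metrics(tp: int, fp: int, tn: int, fn: int
                      ) -> tuple[float, float, float]:
    """(precision, recall, accuracy); undefined ratios reported as NaN."""
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else float("nan")
    return precision, recall, accuracy


def cross_validate(train: LabeledSet, folds: int = 9, threshold: float = 0.8,
                   seed: int = 0, classifier=None
                   ) -> tuple[float, float, float]:
    """Stratified k-fold CV; metrics pooled over all folds' predictions.

    Precision = TP/(TP+FP), recall = TP/(TP+FN), accuracy = (TP+TN)/n over
    the pooled confusion matrix (with 18 positives over 9 folds, per-fold
    metrics would rest on 2 positives each and be uninterpretable).

    ``classifier`` optionally replaces the NB fit/predict pair: a callable
    ``(train_set) -> (test_X -> list of labels)`` for pluggable models.
    """
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(train.y, folds, rng)
    tp = fp = tn = fn = 0
    for k in range(folds):
        test_mask = fold_of == k
        fit_set = LabeledSet(X=train.X[~test_mask], y=train.y[~test_mask],
                             ids=[i for i, m in zip(train.ids, test_mask)
                                  if not m])
        if classifier is None:
            model = nb_fit(fit_set, threshold=threshold)
            pred, _ = nb_classify_matrix(model, train.X[test_mask])
        else:
            pred = classifier(fit_set)(train.X[test_mask])
        truth = train.y[test_mask]
        for t, p in zip(truth, pred):
            if t == 1 and p == POSITIVE:
                tp += 1
            elif t == 1:
                fn += 1
            elif p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return confusion_metrics(tp, fp, tn, fn)
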