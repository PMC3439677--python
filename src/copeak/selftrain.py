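"""Self-training semi-supervised wrapper around the Bernoulli NB classifier.

Starting from the small labeled set L0 = (validated positives P) union (an
equal-sized random draw from the negative pool N), each iteration fits the
base classifier on L_t, promotes the m unlabeled candidates it is most
confident are positive into L as pseudo-positives, and balances them with m
fresh random negatives from the reservoir. Iteration stops when no
unlabeled instance remains, the negative reservoir cannot supply a full
draw, or the iteration cap is reached; the final classifier is then applied
to the remaining unlabeled instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classify import (LabeledSet, NBModel, nb_classify_matrix, nb_fit,
                       nb_posterior_matrix)


@dataclass
class IterationRecord:
    """State snapshot taken after fitting C_t, before promotion."""

    t: int
    n_labeled: int
    n_unlabeled: int
    n_reservoir: int
    promoted_ids: list[str]          # instances promoted *by* this iteration
    positive_ids: list[str]          # current positive calls (pseudo + U hits)


@dataclass
class SelfTrainResult:
    model: NBModel                   # final classifier
    labeled: LabeledSet              # final L
    labels: dict[str, str]           # remaining-U id -> positive/negative
    posteriors: dict[str, float]     # remaining-U id -> P(positive | x)
    history: list[IterationRecord] = field(default_factory=list)
    stop_reason: str = ""


def self_train(pos_X: np.ndarray, pos_ids: Sequence[str],
               neg_X: np.ndarray, neg_ids: Sequence[str],
               unl_X: np.ndarray, unl_ids: Sequence[str],
               m: int = 5, max_iter: int = 75, threshold: float = 0.8,
               seed: int = 0) -> SelfTrainResult:
    """Run the self-training loop. ``m`` = instances promoted per iteration.

    With m = 0 the loop degenerates to plain supervised NB on L0 (the
    returned model is bit-identical to ``nb_fit`` on ``result.labeled``).
    """
    pos_X = np.asarray(pos_X, dtype=np.int8)
    neg_X = np.asarray(neg_X, dtype=np.int8)
    unl_X = np.asarray(unl_X, dtype=np.int8)
    if unl_X.shape[0] == 0:
        raise ValueError("unlabeled pool is empty")
    if neg_X.shape[0] < pos_X.shape[0]:
        raise ValueError("negative pool smaller than positive set")

    rng = np.random.default_rng(seed)

    # L0: all positives + an equal number of random negatives (l_n = l_p)
    init = np.sort(rng.choice(neg_X.shape[0], size=pos_X.shape[0],
                              replace=False))
    reservoir_mask = np.ones(neg_X.shape[0], dtype=bool)
    reservoir_mask[init] = False

    L_X = [pos_X, neg_X[init]]
    L_y = [np.ones(pos_X.shape[0], dtype=np.int8),
           np.zeros(init.shape[0], dtype=np.int8)]
    L_ids = list(pos_ids) + [neg_ids[i] for i in init]

    U_idx = list(range(unl_X.shape[0]))
    promoted_ids: list[str] = []
    history: list[IterationRecord] = []
    t = 0
    stop_reason = ""

    while True:
        labeled = LabeledSet(X=np.vstack(L_X), y=np.concatenate(L_y),
                             ids=list(L_ids))
        model = nb_fit(labeled, threshold=threshold)

        if U_idx:
            post = nb_posterior_matrix(model, unl_X[U_idx])
            u_positive = [unl_ids[i] for i, p in zip(U_idx, post)
                          if p >= threshold]
        else:
            post = np.empty(0)
            u_positive = []
        history.append(IterationRecord(
            t=t, n_labeled=len(labeled), n_unlabeled=len(U_idx),
            n_reservoir=int(reservoir_mask.sum()),
            promoted_ids=[], positive_ids=sorted(promoted_ids + u_positive)))

        if not U_idx:
            stop_reason = "unlabeled pool exhausted"
            break
        if t >= max_iter:
            stop_reason = "maximum number of iterations reached"
            break
        if m == 0:
            stop_reason = "m = 0 (supervised reduction)"
            break
        k = min(m, len(U_idx))
        if int(reservoir_mask.sum()) < k:
            stop_reason = "negative reservoir exhausted"
            break

        # promote the k most confidently positive instances; posterior ties
        # break by ascending candidate id for determinism
        order = sorted(range(len(U_idx)),
                       key=lambda i: (-post[i], unl_ids[U_idx[i]]))
        take = [U_idx[i] for i in order[:k]]
        take_ids = [unl_ids[i] for i in take]

        avail = np.flatnonzero(reservoir_mask)
        drawn = np.sort(rng.choice(avail, size=k, replace=False))
        reservoir_mask[drawn] = False

        L_X.extend([unl_X[take], neg_X[drawn]])
        L_y.extend([np.ones(k, dtype=np.int8), np.zeros(k, dtype=np.int8)])
        L_ids.extend(take_ids)
        L_ids.extend(neg_ids[i] for i in drawn)

        taken = set(take)
        U_idx = [i for i in U_idx if i not in taken]
        promoted_ids.extend(take_ids)
        history[-1].promoted_ids = take_ids
        t += 1

    # apply the final classifier to what remains of U
    labels: dict[str, str] = {}
    posteriors: dict[str, float] = {}
    if U_idx:
        pred, post = nb_classify_matrix(model, unl_X[U_idx])
        for i, lab, p in zip(U_idx, pred, post):
            labels[unl_ids[i]] = lab
            posteriors[unl_ids[i]] = float(p)
    return SelfTrainResult(model=model, labeled=labeled, labels=labels,
                           posteriors=posteriors, history=history,
                           stop_reason=stop_reason)


def evaluate_history(history: Sequence[IterationRecord],
                     evaluator: Callable[[list[str]], float]
                     ) -> list[tuple[int, int, float, bool]]:
    """Per-iteration motif-containment series for the current positive calls.

    Returns (t, n_positive_calls, ratio, empty_flag) per iteration; an
    empty call set is recorded as ratio 0.0 with the flag raised.
    """
    series = []
    for rec in history:
        if rec.positive_ids:
            series.append((rec.t, len(rec.positive_ids),
                           float(evaluator(rec.positive_ids)), False))
        else:
            series.append((rec.t, 0, 0.0, True))
    return series
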