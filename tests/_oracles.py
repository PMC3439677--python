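"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle deliberately avoids the implementation's code path: trigram
presence by materialising the substring set, peak merging by union-find
connected components, NB posteriors by the direct (non-log) product form,
and PWM scanning by per-offset enumeration on both strands.
"""

from itertools import product

import numpy as np

TRIGRAMS = ["".join(p) for p in product("ACGT", repeat=3)]
_COMP = str.maketrans("ACGTN", "TGCAN")


def trigram_presence_oracle(seq: str) -> np.ndarray:
    substrings = {seq[i:i + 3] for i in range(len(seq) - 2)}
    return np.array([int(t in substrings) for t in TRIGRAMS], dtype=np.int8)


def merge_partition_oracle(peaks):
    """Partition of peak ids into overlap-connected components (union-find)."""
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            a, b = peaks[i], peaks[j]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), set()).add((p.source, p.id))
    return {frozenset(g) for g in groups.values()}


def nb_posterior_oracle(prior_pos, prior_neg, theta_pos, theta_neg, x):
    """Direct product-form Bayes, no logarithms."""
    jp = prior_pos * np.prod(np.where(x, theta_pos, 1.0 - theta_pos))
    jn = prior_neg * np.prod(np.where(x, theta_neg, 1.0 - theta_neg))
    return jp / (jp + jn)


def scan_oracle(seq: str, log_odds: np.ndarray):
    """Best (score, position, strand) by enumerating every window on both
    strands; reverse-strand windows are scored as the reverse complement of
    the forward window under the forward matrix."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = log_odds.shape[0]
    best = (float("-inf"), None, None)

    def window_score(window: str) -> float:
        score = 0.0
        for i, b in enumerate(window):
            if b not in base_idx:
                return float("-inf")
            score += log_odds[i, base_idx[b]]
        return score

    for pos in range(len(seq) - w + 1):
        window = seq[pos:pos + w]
        for strand, oriented in (("+", window),
                                 ("-", window.translate(_COMP)[::-1])):
            score = window_score(oriented)
            if score > best[0] or (
                    score == best[0] and best[1] is not None and (
                        pos < best[1] or (pos == best[1] and strand == "+"))):
                best = (score, pos, strand)
    if not np.isfinite(best[0]):
        return (float("-inf"), None, None)
    return best


def window_score_at(seq: str, log_odds: np.ndarray, pos: int,
                    strand: str) -> float:
    """Score of one specific window/strand, for verifying reported hits."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    window = seq[pos:pos + log_odds.shape[0]]
    if strand == "-":
        window = window.translate(_COMP)[::-1]
    score = 0.0
    for i, b in enumerate(window):
        if b not in base_idx:
            return float("-inf")
        score += log_odds[i, base_idx[b]]
    return score


def best_two_partition_inertia(X: np.ndarray) -> float:
    """Exhaustive best L1 inertia over all 2-partitions with median
    centroids (n <= 12)."""
    n = X.shape[0]
    best = float("inf")
    for mask in range(1, 2 ** (n - 1)):
        members = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        if members.all() or not members.any():
            continue
        inertia = 0.0
        for part in (X[members], X[~members]):
            med = np.median(part, axis=0)
            inertia += np.abs(part - med).sum()
        best = min(best, inertia)
    return best


def random_dna(rng: np.random.Generator, length: int,
               n_prob: float = 0.0) -> str:
    alphabet = "ACGTN"
    probs = [(1 - n_prob) / 4] * 4 + [n_prob]
    return "".join(rng.choice(list(alphabet), size=length, p=probs))
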