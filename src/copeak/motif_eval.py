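"""ERE motif containment via PWM scanning.

Predicted peak sets are judged by the fraction of peaks whose +/-300 bp
summit window contains a match to the estrogen response element (ERE), the
palindromic motif GGTCAnnnTGACC bound by ER-alpha. Matching is a best-hit
log2-odds scan over both strands; a window "contains" the motif when the
best hit reaches ``score_threshold_frac`` (default 0.8) of the maximum
achievable score. The default matrix is built from the consensus: count 10
for the consensus base at fixed positions, the three spacer positions
uniform; any JASPAR-style plain-text PFM can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .features import extract_window
from .io_formats import Genome, Peak

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# complement permutation of the A,C,G,T column order
_COMP_COLS = [3, 2, 1, 0]

ERE_CONSENSUS = "GGTCANNNTGACC"


@dataclass
class PWM:
    """Position weight matrix with a max-score-fraction containment rule."""

    frequencies: np.ndarray        # (width, 4) rows sum to 1
    log_odds: np.ndarray           # (width, 4) log2(freq / background)
    score_threshold_frac: float = 0.8

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        """Score of the consensus sequence: row-wise maximum sum."""
        return float(self.log_odds.max(axis=1).sum())


class ScanHit(NamedTuple):
    score: float
    position: int | None
    strand: str | None


NO_HIT = ScanHit(float("-inf"), None, None)


def pwm_from_counts(counts, pseudocount: float = 0.5,
                    background: Sequence[float] | None = None,
                    score_threshold_frac: float = 0.8) -> PWM:
    """Build a PWM from a (width x 4) count matrix.

    Frequencies are pseudocount-regularized per row; log-odds are log2
    against the background (uniform by default).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be a (width, 4) matrix over A,C,G,T")
    if counts.shape[0] < 4:
        raise ValueError("motif width must be at least 4")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    bg = np.full(4, 0.25) if background is None else np.asarray(background,
                                                                dtype=float)
    freqs = (counts + pseudocount) / \
        (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    log_odds = np.log2(freqs / bg)
    return PWM(frequencies=freqs, log_odds=log_odds,
               score_threshold_frac=score_threshold_frac)


def default_ere_pwm(score_threshold_frac: float = 0.8) -> PWM:
    """ERE matrix from the palindromic consensus GGTCAnnnTGACC.

    Count 10 for the consensus base at the ten fixed positions, all-zero
    rows (uniform after pseudocount) at the three spacer positions.
    """
    counts = np.zeros((len(ERE_CONSENSUS), 4))
    for i, base in enumerate(ERE_CONSENSUS):
        if base in _BASE_INDEX:
            counts[i, _BASE_INDEX[base]] = 10.0
    return pwm_from_counts(counts, score_threshold_frac=score_threshold_frac)


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) ==
              ord(base)] = idx
    return codes


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score of every offset; windows containing a non-ACGT base get -inf."""
    w = matrix.shape[0]
    n = codes.shape[0] - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, float("-inf"))
    if valid.any():
        rows = np.arange(w)
        scores[valid] = matrix[rows, windows[valid]].sum(axis=1)
    return scores


def scan(seq: str, pwm: PWM) -> ScanHit:
    """Best hit over all offsets on both strands.

    The reverse strand is scanned with the reverse-complemented matrix, so
    positions are forward-strand window starts. Ties break leftmost, then
    forward strand first. Sequences shorter than the motif return no hit.
    """
    if len(seq) < pwm.width:
        return NO_HIT
    codes = _encode(seq.upper())
    rc_matrix = pwm.log_odds[::-1][:, _COMP_COLS]
    best = NO_HIT
    for matrix, strand in ((pwm.log_odds, "+"), (rc_matrix, "-")):
        scores = _window_scores(codes, matrix)
        pos = int(scores.argmax())
        hit = ScanHit(float(scores[pos]), pos, strand)
        if best.position is None or hit.score > best.score or \
                (hit.score == best.score and hit.position < best.position):
            best = hit
    if not np.isfinite(best.score):
        return NO_HIT
    return best


def contains_motif(peak: Peak, genome: Genome, pwm: PWM,
                   flank: int = 300) -> bool:
    """True iff the summit +/-flank window has a hit at or above the
    max-score-fraction threshold."""
    window = extract_window(genome, peak.chrom, peak.summit, flank)
    hit = scan(window, pwm)
    if hit.position is None:
        return False
    if pwm.score_threshold_frac <= 0:
        return True          # degenerate bound: any scoreable window passes
    return hit.score >= pwm.score_threshold_frac * pwm.max_score


def ere_ratio(peaks: Sequence[Peak], genome: Genome, pwm: PWM,
              flank: int = 300) -> tuple[int, int, float]:
    """(n_total, n_with_motif, ratio), ratio at full precision.

    An empty peak set gives an undefined ratio, reported as NaN with
    n_total = 0. Presentation rounding (2 dp) belongs to the report layer.
    """
    n_total = len(peaks)
    if n_total == 0:
        return 0, 0, float("nan")
    n_with = sum(contains_motif(p, genome, pwm, flank=flank) for p in peaks)
    return n_total, n_with, n_with / n_total


def read_jaspar_pfm(path, score_threshold_frac: float = 0.8) -> PWM:
    """Read a JASPAR-style plain-text PFM.

    Accepts both the bracketed layout (``A  [ 10  0 ... ]``) and four bare
    whitespace-separated count rows in A, C, G, T order, with an optional
    ``>`` header line.
    """
    rows: dict[str, list[float]] = {}
    bare: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            if line[0] in BASES and ("[" in line or line[1:2].isspace()):
                base = line[0]
                body = line[1:].replace("[", " ").replace("]", " ")
                rows[base] = [float(v) for v in body.split()]
            else:
                bare.append([float(v) for v in line.replace(
                    "[", " ").replace("]", " ").split()])
    if len(rows) == 4:
        matrix = np.array([rows[b] for b in BASES])
    elif len(bare) == 4:
        matrix = np.array(bare)
    else:
        raise ValueError(f"{path}: expected four count rows (A,C,G,T)")
    return pwm_from_counts(matrix.T,
                           score_threshold_frac=score_threshold_frac)


def write_jaspar_pfm(pwm_counts: np.ndarray, name: str, path) -> None:
    counts = np.asarray(pwm_counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in counts[:, i])
            fh.write(f"{base} [ {vals} ]\n")
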