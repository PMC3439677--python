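"""The 67-dimensional binary feature encoding of a candidate peak.

Layout (fixed, versioned by name order):

* indices 0-63 — presence/absence of each nucleotide trigram (lexicographic
  AAA..TTT) in the 600 bp window centered on the peak summit; sequence
  information intrinsic to regulatory sites.
* index 64 — nucleosome-occupancy bit: 1 iff the mean predicted occupancy
  over +/-50 bp of the summit (one nucleosome length) exceeds 0.75.
* index 65 — primary-TF bit: 1 iff the peak shares >= 1 bp with any ER-alpha
  ChIP-seq peak.
* index 66 — functional-outcome bit: 1 iff the nearest-TSS gene of the
  summit is co-regulator-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneRecord, Genome, OccupancyTrack, Peak
from .peak_pool import CandidatePool, overlaps

TRIGRAMS: list[str] = ["".join(p) for p in product("ACGT", repeat=3)]
FEATURE_NAMES: list[str] = [f"tri_{t}" for t in TRIGRAMS] + [
    "occ", "er_overlap", "sensitive_gene"]
N_FEATURES = 67

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class FeatureConfig:
    """Window sizes and thresholds for feature extraction.

    seq_flank: half-width (bp) of the summit-centered sequence window for
        the trigram block; default 300 (600 bp total).
    occ_flank: half-width (bp) of the occupancy window; default 50, i.e.
        101 positions inclusive of both endpoints.
    occ_threshold: strict lower bound on the window mean for the occupancy
        bit; default 0.75.
    gene_max_distance: optional cap (bp) on summit-to-TSS distance for gene
        mapping; None = nearest gene regardless of distance.
    both_strands: also scan the reverse complement for trigram presence
        (off by default; the forward scan is the canonical encoding).
    """

    seq_flank: int = 300
    occ_flank: int = 50
    occ_threshold: float = 0.75
    gene_max_distance: int | None = None
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.seq_flank <= 0 or self.occ_flank <= 0:
            raise ValueError("flanks must be positive")
        if not (0.0 < self.occ_threshold < 1.0):
            raise ValueError("occ_threshold must be in (0, 1)")


def extract_window(genome: Genome, chrom: str, summit: int, flank: int) -> str:
    """Sequence of [summit-flank, summit+flank) clamped at chromosome edges.

    Clamped, never padded: near an edge the window is simply shorter.
    """
    if chrom not in genome:
        raise KeyError(f"chrom {chrom!r} not in genome")
    seq = genome.sequences[chrom]
    if not (0 <= summit < len(seq)):
        raise ValueError(
            f"summit {summit} outside chrom {chrom!r} of length {len(seq)}")
    return seq[max(0, summit - flank):min(len(seq), summit + flank)]


def trigram_presence(seq: str, both_strands: bool = False) -> np.ndarray:
    """64-element 0/1 vector: presence of each trigram in ``seq``.

    All overlapping length-3 substrings are scanned on the forward strand;
    windows containing N never match. Sequences shorter than 3 give all
    zeros.
    """
    out = np.zeros(64, dtype=np.int8)
    _scan_trigrams(seq, out)
    if both_strands:
        _scan_trigrams(seq.translate(_COMPLEMENT)[::-1], out)
    return out


def _scan_trigrams(seq: str, out: np.ndarray) -> None:
    codes = [_BASE_INDEX.get(b, -1) for b in seq]
    for i in range(len(codes) - 2):
        a, b, c = codes[i], codes[i + 1], codes[i + 2]
        if a < 0 or b < 0 or c < 0:
            continue
        out[(a << 4) | (b << 2) | c] = 1


def occupancy_bit(track: OccupancyTrack, chrom: str, summit: int,
                  flank: int = 50, threshold: float = 0.75,
                  chrom_length: int | None = None) -> int:
    """1 iff mean occupancy over [summit-flank, summit+flank] (inclusive,
    clamped at chromosome edges) is strictly greater than ``threshold``."""
    mean = track.window_mean(chrom, summit - flank, summit + flank + 1,
                             chrom_length=chrom_length)
    return int(mean > threshold)


def er_overlap_bit(peak: Peak, er_peaks: Iterable[Peak]) -> int:
    """1 iff the peak shares at least one base pair with any primary-TF peak."""
    return int(any(overlaps(peak, e) for e in er_peaks))


def map_peak_to_gene(peak: Peak, genes: Sequence[GeneRecord],
                     max_distance: int | None = None) -> GeneRecord | None:
    """Nearest-TSS gene of the peak summit on the same chromosome.

    Distance ties break to the smaller TSS, then lexicographic gene id;
    returns None when no same-chromosome gene exists or the nearest TSS is
    farther than ``max_distance``.
    """
    best: GeneRecord | None = None
    best_key: tuple[int, int, str] | None = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        key = (abs(g.tss - peak.summit), g.tss, g.gene_id)
        if best_key is None or key < best_key:
            best, best_key = g, key
    if best is None:
        return None
    if max_distance is not None and best_key[0] > max_distance:
        return None
    return best


def sensitive_gene_bit(peak: Peak, genes: Sequence[GeneRecord],
                       max_distance: int | None = None) -> int:
    """1 iff the mapped (nearest-TSS) gene exists and is sensitive."""
    gene = map_peak_to_gene(peak, genes, max_distance)
    return int(gene is not None and gene.sensitive)


def build_feature_vector(peak: Peak, genome: Genome, track: OccupancyTrack,
                         er_peaks: Sequence[Peak],
                         genes: Sequence[GeneRecord],
                         config: FeatureConfig | None = None) -> np.ndarray:
    config = config or FeatureConfig()
    if peak.chrom not in genome:
        raise KeyError(
            f"peak {peak.id!r}: chrom {peak.chrom!r} not in genome")
    window = extract_window(genome, peak.chrom, peak.summit, config.seq_flank)
    vec = np.empty(N_FEATURES, dtype=np.int8)
    vec[:64] = trigram_presence(window, both_strands=config.both_strands)
    vec[64] = occupancy_bit(track, peak.chrom, peak.summit,
                            flank=config.occ_flank,
                            threshold=config.occ_threshold,
                            chrom_length=genome.lengths[peak.chrom])
    vec[65] = er_overlap_bit(peak, er_peaks)
    vec[66] = sensitive_gene_bit(peak, genes, config.gene_max_distance)
    return vec


def build_feature_matrix(peaks: CandidatePool | Sequence[Peak],
                         genome: Genome, track: OccupancyTrack,
                         er_peaks: Sequence[Peak],
                         genes: Sequence[GeneRecord],
                         config: FeatureConfig | None = None
                         ) -> tuple[list[str], np.ndarray]:
    """One 67-element row per peak, in pool order. Returns (ids, matrix)."""
    peak_list = list(peaks.peaks if isinstance(peaks, CandidatePool) else peaks)
    config = config or FeatureConfig()
    # pre-bucket primary-TF peaks by chrom: the overlap test is the hot loop
    er_by_chrom: dict[str, list[Peak]] = {}
    for e in er_peaks:
        er_by_chrom.setdefault(e.chrom, []).append(e)
    ids: list[str] = []
    matrix = np.empty((len(peak_list), N_FEATURES), dtype=np.int8)
    for i, peak in enumerate(peak_list):
        matrix[i] = build_feature_vector(
            peak, genome, track, er_by_chrom.get(peak.chrom, ()), genes,
            config)
        ids.append(peak.id)
    return ids, matrix
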