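"""Readers and writers for every on-disk format the pipeline touches.

Coordinate conventions are strict throughout the package: intervals are
0-based half-open ``[start, end)`` (the native BED convention, so no shift
on ingest) and peak summits are stored as *absolute* genomic positions, not
offsets, so that window extraction is independent of which caller produced
the peak.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

_VALID_BASES = re.compile(r"[^ACGTN]")

PEAK_DIALECTS = ("bed6+summit", "narrowPeak")


@dataclass(frozen=True)
class Peak:
    """A candidate binding interval.

    ``start``/``end`` are 0-based half-open; ``summit`` is an absolute
    0-based genomic position with ``start <= summit < end``. ``score`` is
    caller-specific (e.g. -log10 p) and only used for relative ordering.
    """

    id: str
    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"peak {self.id!r}: empty chrom")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"peak {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.id!r}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """In-memory genome: uppercase DNA over {A,C,G,T,N}, keyed by chrom."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class OccupancyTrack:
    """Per-base nucleosome-occupancy probabilities in [0, 1].

    Positions not covered by any bedGraph interval default to 0.0 — a
    conservative "no occupancy evidence" value.
    """

    values: dict[str, np.ndarray] = field(default_factory=dict)

    def window_mean(self, chrom: str, lo: int, hi: int,
                    chrom_length: int | None = None) -> float:
        """Mean value over positions [lo, hi) clamped to the chromosome.

        Positions beyond the stored array (but inside the chromosome)
        count as 0.0.
        """
        lo = max(0, lo)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        if hi <= lo:
            return 0.0
        arr = self.values.get(chrom)
        total = 0.0
        if arr is not None and lo < arr.shape[0]:
            total = float(arr[lo:min(hi, arr.shape[0])].sum())
        return total / (hi - lo)


@dataclass(frozen=True)
class GeneRecord:
    """A gene TSS with its co-regulator-sensitivity label."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    sensitive: bool

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative TSS")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad {what} {text!r}") from exc


def read_peaks(path, source_label: str, dialect: str) -> list[Peak]:
    """Read a peak file in one of two dialects.

    ``bed6+summit``: chrom start end name score strand [summit], where the
    optional 7th column is an *absolute* summit position (-1 -> midpoint).

    ``narrowPeak``: the ENCODE 10-column format; column 10 is the summit
    offset relative to ``start`` (-1 -> midpoint).
    """
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {PEAK_DIALECTS}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            try:
                peaks.append(_parse_peak_row(cols, source_label, dialect, lineno))
            except ValueError as exc:
                raise ValueError(f"{path}: {exc}") from exc
    return peaks


def _parse_peak_row(cols: list[str], source: str, dialect: str,
                    lineno: int) -> Peak:
    min_cols = 10 if dialect == "narrowPeak" else 6
    if len(cols) < min_cols:
        raise ValueError(
            f"line {lineno}: expected >= {min_cols} columns for {dialect}, "
            f"got {len(cols)}"
        )
    chrom = cols[0]
    start = _parse_int(cols[1], "start", lineno)
    end = _parse_int(cols[2], "end", lineno)
    if not (0 <= start < end):
        raise ValueError(f"line {lineno}: invalid interval [{start}, {end})")
    name = cols[3] if cols[3] not in (".", "") else f"{source}_{lineno}"
    try:
        score = float(cols[4]) if cols[4] != "." else 0.0
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad score {cols[4]!r}") from exc

    if dialect == "narrowPeak":
        offset = _parse_int(cols[9], "summit offset", lineno)
        summit = start + offset if offset >= 0 else (start + end) // 2
    else:
        if len(cols) >= 7:
            abs_summit = _parse_int(cols[6], "summit", lineno)
            summit = abs_summit if abs_summit >= 0 else (start + end) // 2
        else:
            summit = (start + end) // 2
    if not (start <= summit < end):
        raise ValueError(
            f"line {lineno}: summit {summit} outside [{start}, {end})"
        )
    return Peak(id=name, chrom=chrom, start=start, end=end, summit=summit,
                score=score, source=source)


def write_peaks(peaks: list[Peak], path) -> None:
    """Write peaks in the bed6+summit dialect (round-trips through read_peaks)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{p.score:g}\t.\t"
                     f"{p.summit}\n")


def read_fasta(path) -> Genome:
    """Read a FASTA file; uppercase, non-ACGTN letters mapped to N."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"{path}: duplicate chrom {rec.id!r}")
        seq = _VALID_BASES.sub("N", str(rec.seq).upper())
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return Genome(sequences=sequences)


def read_occupancy(path, genome: Genome | None = None) -> OccupancyTrack:
    """Read a bedGraph of per-base occupancy probabilities.

    Intervals must be non-overlapping per chromosome with values in [0, 1];
    uncovered positions default to 0.0. When a genome is supplied, arrays
    are sized to the chromosome lengths.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            chrom = cols[0]
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            try:
                value = float(cols[3])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad value {cols[3]!r}") from exc
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"{path}: line {lineno}: value {value} outside [0, 1]")
            if not (0 <= start < end):
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})")
            intervals.setdefault(chrom, []).append((start, end, value))

    track = OccupancyTrack()
    for chrom, ivs in intervals.items():
        ivs.sort()
        prev_end = -1
        for start, end, _ in ivs:
            if start < prev_end:
                raise ValueError(
                    f"{path}: overlapping intervals on {chrom} at {start}")
            prev_end = end
        size = ivs[-1][1]
        if genome is not None and chrom in genome:
            size = genome.lengths[chrom]
        arr = np.zeros(size, dtype=np.float64)
        for start, end, value in ivs:
            arr[start:end] = value
        track.values[chrom] = arr
    return track


def read_genes(path, sensitive_ids_path=None) -> list[GeneRecord]:
    """Read a gene table TSV: gene_id, chrom, tss, strand [, sensitive].

    A separate sensitive-gene id list (one id per line) overrides or
    supplements the optional ``sensitive`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sensitive_ids: set[str] = set()
    if sensitive_ids_path is not None:
        with open(sensitive_ids_path) as fh:
            sensitive_ids = {line.strip() for line in fh if line.strip()}
    genes = []
    for row in df.itertuples(index=False):
        sensitive = bool(getattr(row, "sensitive", 0)) or row.gene_id in sensitive_ids
        genes.append(GeneRecord(gene_id=row.gene_id, chrom=row.chrom,
                                tss=int(row.tss), strand=row.strand,
                                sensitive=sensitive))
    return genes


def write_genes(genes: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tsensitive\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t"
                     f"{int(g.sensitive)}\n")


CLASSIFIED_HEADER = ["id", "chrom", "start", "end", "summit", "label",
                     "posterior"]


def write_classified_peaks(peaks: list[Peak], labels: list[str],
                           posteriors, path) -> None:
    """Write one row per peak: id, coordinates, label, posterior P(positive)."""
    if not (len(peaks) == len(labels) == len(posteriors)):
        raise ValueError(
            f"length mismatch: {len(peaks)} peaks, {len(labels)} labels, "
            f"{len(posteriors)} posteriors"
        )
    for lab in labels:
        if lab not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {lab!r}")
    with open(path, "w") as fh:
        fh.write("\t".join(CLASSIFIED_HEADER) + "\n")
        for p, lab, post in zip(peaks, labels, posteriors):
            fh.write(f"{p.id}\t{p.chrom}\t{p.start}\t{p.end}\t{p.summit}\t"
                     f"{lab}\t{post!r}\n")


def read_classified_peaks(path) -> tuple[list[Peak], list[str], np.ndarray]:
    """Inverse of :func:`write_classified_peaks` (label- and posterior-lossless)."""
    peaks, labels, posteriors = [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CLASSIFIED_HEADER:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            peaks.append(Peak(id=cols[0], chrom=cols[1], start=int(cols[2]),
                              end=int(cols[3]), summit=int(cols[4])))
            labels.append(cols[5])
            posteriors.append(float(cols[6]))
    return peaks, labels, np.asarray(posteriors)


def write_feature_matrix(ids: list[str], matrix: np.ndarray, path,
                         feature_names: list[str]) -> None:
    """Write the binary feature matrix as TSV with an ``id`` + 67-name header."""
    if matrix.shape[0] != len(ids):
        raise ValueError("row count does not match number of ids")
    if matrix.shape[1] != len(feature_names):
        raise ValueError("column count does not match feature names")
    df = pd.DataFrame(matrix, columns=feature_names)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path) -> tuple[list[str], np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    ids = df["id"].tolist()
    names = [c for c in df.columns if c != "id"]
    return ids, df[names].to_numpy(dtype=np.int8), names
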