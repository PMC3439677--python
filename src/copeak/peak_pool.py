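"""Candidate-peak pool: union of multiple callers' peak sets.

Peak callers disagree widely on weak co-regulator signal, so instead of
picking one "best" caller the pipeline pools every caller's output and lets
the classifier sort candidates out. Peaks sharing at least one base pair on
the same chromosome are merged transitively into a single candidate — the
same >= 1 bp criterion used for primary-TF overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, Sequence

from .io_formats import Peak


@dataclass
class CandidatePool:
    """Merged candidates plus the provenance of each merge."""

    peaks: list[Peak]
    provenance: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def overlaps(a: Peak, b: Peak) -> bool:
    """True iff the two peaks share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def union_peaks(peak_sets: Sequence[Iterable[Peak]]) -> CandidatePool:
    """Merge all peak sets into a pool of non-overlapping candidates.

    Transitively merged candidates span min(start)..max(end); the candidate
    summit comes from the highest-scoring contributor (ties -> leftmost
    summit) and the source label is the comma-joined sorted set of
    contributing callers.
    """
    all_peaks = sorted(chain.from_iterable(peak_sets),
                       key=lambda p: (p.chrom, p.start, p.end, p.id))
    candidates: list[Peak] = []
    provenance: dict[str, set[tuple[str, str]]] = {}
    group: list[Peak] = []

    def flush(group: list[Peak]) -> None:
        idx = len(candidates)
        cid = f"cand_{idx:05d}"
        # summit of the highest-scoring contributor, ties -> leftmost summit
        best = min(group, key=lambda p: (-p.score, p.summit))
        cand = Peak(
            id=cid,
            chrom=group[0].chrom,
            start=min(p.start for p in group),
            end=max(p.end for p in group),
            summit=best.summit,
            score=max(p.score for p in group),
            source=",".join(sorted({p.source for p in group})),
        )
        candidates.append(cand)
        provenance[cid] = {(p.source, p.id) for p in group}

    for peak in all_peaks:
        if group and peak.chrom == group[-1].chrom and \
                peak.start < max(p.end for p in group):
            group.append(peak)
        else:
            if group:
                flush(group)
            group = [peak]
    if group:
        flush(group)
    return CandidatePool(peaks=candidates, provenance=provenance)


def intersect_counts(pools: dict[str, Iterable[Peak]]) -> dict[tuple[str, ...], int]:
    """Venn accounting over merged candidates.

    For every non-empty subset of the pool names, counts the merged
    candidates supported by *exactly* that subset of callers. The cells sum
    to the total number of merged candidates.
    """
    names = sorted(pools)
    if len(names) < 2:
        raise ValueError("need at least two named peak sets")
    relabeled = [
        [Peak(id=p.id, chrom=p.chrom, start=p.start, end=p.end,
              summit=p.summit, score=p.score, source=name)
         for p in pools[name]]
        for name in names
    ]
    pool = union_peaks(relabeled)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            counts[subset] = 0
    for cand in pool.peaks:
        sources = tuple(sorted({src for src, _ in pool.provenance[cand.id]}))
        counts[sources] += 1
    return counts
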