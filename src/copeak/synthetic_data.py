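"""Self-contained synthetic dataset with the signal structure the
classifier assumes.

The generator emulates a co-regulator ChIP-seq study on a toy genome:
*true* sites carry the planted ERE consensus, overlap primary-TF (ER-alpha)
peaks, sit in high-nucleosome-occupancy windows and lie near
co-regulator-sensitive genes with high probability; *decoy* sites carry all
of these with low probability. Three pseudo-callers report every site with
independent miss rates and jittered summits, an IgG-like negative pool is
drawn away from all sites, and a small validated-positive set mimics the
qPCR-confirmed training peaks. Every output file is reproducible
byte-exactly from the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import confusion_metrics
from .io_formats import GeneRecord, Peak, write_genes, write_peaks
from .motif_eval import ERE_CONSENSUS
from .peak_pool import CandidatePool

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_GAP = 2000          # sites at least 2 kb apart: no accidental merges
_EDGE_MARGIN = 2000
_OCC_HALF = 150          # half-width of the occupancy plateau per site
_SITE_HALF = 150         # half-width of labeled-positive / negative peaks

CALLER_NAMES = ("callerA", "callerB", "callerC")


@dataclass
class SynthConfig:
    """Generative parameters; defaults are the study conditions.

    Probabilities are per-site Bernoulli rates, split by true/decoy class.
    ``genome_length`` is bp per chromosome; 600 default sites at >= 2 kb
    spacing need ~600 kb of span per chromosome, hence 1 Mb chromosomes.
    """

    seed: int = 0
    n_chroms: int = 2
    genome_length: int = 1_000_000
    n_true_sites: int = 200
    n_decoy_sites: int = 400
    p_plant_motif_true: float = 0.9
    p_plant_motif_decoy: float = 0.1
    p_er_overlap_true: float = 0.8
    p_er_overlap_decoy: float = 0.1
    occ_mean_true: float = 0.85
    occ_mean_decoy: float = 0.5
    p_sensitive_gene_true: float = 0.6
    p_sensitive_gene_decoy: float = 0.05
    caller_fnr: float = 0.2
    summit_jitter_sd: float = 20.0
    n_labeled_pos: int = 18
    n_negative_pool: int = 500

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name.startswith(("p_", "caller_fnr")) and not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """Paths and in-memory handles for one generated bundle."""

    config: SynthConfig
    outdir: Path
    paths: dict[str, Path]
    truth: pd.DataFrame       # site_id, chrom, center, is_true, ...


def _place_sites(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n sorted centers in [margin, length-margin] with >= 2 kb spacing."""
    span = length - 2 * _EDGE_MARGIN
    slack = span - (n - 1) * _MIN_GAP
    if slack < 0:
        raise ValueError(
            f"genome too short to place {n} sites {_MIN_GAP} bp apart "
            f"(need {2 * _EDGE_MARGIN + (n - 1) * _MIN_GAP} bp, have {length})")
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return (_EDGE_MARGIN + np.floor(u) + np.arange(n) * _MIN_GAP).astype(int)


def generate(config: SynthConfig, outdir) -> SyntheticDataset:
    """Write the full dataset bundle to ``outdir``; see the module docstring."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    n_sites = config.n_true_sites + config.n_decoy_sites

    # genome bases (ASCII byte arrays), then site placement, in a fixed order
    base_codes = {c: _BASES[rng.integers(0, 4, size=config.genome_length)]
                  for c in chroms}
    per_chrom = [n_sites // config.n_chroms + (1 if i < n_sites %
                 config.n_chroms else 0) for i in range(config.n_chroms)]
    centers = {c: _place_sites(rng, k, config.genome_length)
               for c, k in zip(chroms, per_chrom)}

    flags = np.zeros(n_sites, dtype=bool)
    flags[:config.n_true_sites] = True
    flags = rng.permutation(flags)

    sites = []           # (site_id, chrom, center, is_true)
    i = 0
    for chrom in chroms:
        for center in centers[chrom]:
            sites.append((f"site_{i:04d}", chrom, int(center), bool(flags[i])))
            i += 1

    # plant the ERE consensus (random 3-bp spacer) at selected sites
    motif_fixed = np.frombuffer(
        ERE_CONSENSUS.replace("N", "A").encode(), dtype=np.uint8)
    planted = []
    for site_id, chrom, center, is_true in sites:
        p = config.p_plant_motif_true if is_true else config.p_plant_motif_decoy
        plant = bool(rng.random() < p)
        planted.append(plant)
        if plant:
            instance = motif_fixed.copy()
            instance[5:8] = _BASES[rng.integers(0, 4, size=3)]
            start = center - len(ERE_CONSENSUS) // 2
            base_codes[chrom][start:start + len(instance)] = instance

    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for chrom in chroms:
            fh.write(f">{chrom}\n")
            seq = base_codes[chrom].tobytes().decode()
            for j in range(0, len(seq), 80):
                fh.write(seq[j:j + 80] + "\n")

    # three pseudo-callers with independent dropout and summit jitter
    caller_peaks: dict[str, list[Peak]] = {name: [] for name in CALLER_NAMES}
    for name in CALLER_NAMES:
        for site_id, chrom, center, is_true in sites:
            if rng.random() < config.caller_fnr:
                continue
            hl = int(rng.integers(100, 301))
            hr = int(rng.integers(100, 301))
            jitter = float(rng.normal(0.0, config.summit_jitter_sd))
            jitter = int(np.clip(jitter, -80, 80))
            summit = int(np.clip(center + jitter, center - hl + 1,
                                 center + hr - 1))
            score = round(float(rng.uniform(1.0, 100.0)), 3)
            caller_peaks[name].append(Peak(
                id=f"{name}_{site_id}", chrom=chrom, start=center - hl,
                end=center + hr, summit=summit, score=score, source=name))
    for name in CALLER_NAMES:
        paths[name] = outdir / f"{name}.bed"
        write_peaks(caller_peaks[name], paths[name])

    # primary-TF (ER-alpha) peaks overlapping sites per class probability
    er_flags = []
    er_peaks: list[Peak] = []
    for site_id, chrom, center, is_true in sites:
        p = config.p_er_overlap_true if is_true else config.p_er_overlap_decoy
        flag = bool(rng.random() < p)
        er_flags.append(flag)
        if flag:
            offset = int(rng.integers(-50, 51))
            hw = int(rng.integers(80, 201))
            er_peaks.append(Peak(
                id=f"er_{site_id}", chrom=chrom,
                start=center + offset - hw, end=center + offset + hw,
                summit=center + offset, score=1.0, source="er"))
    paths["er_peaks"] = outdir / "er_peaks.bed"
    write_peaks(er_peaks, paths["er_peaks"])

    # occupancy plateau (+/-150 bp, per-base uniform noise) per site
    occ_means = []
    paths["occupancy"] = outdir / "occupancy.bedgraph"
    with open(paths["occupancy"], "w") as fh:
        for site_id, chrom, center, is_true in sites:
            mean = config.occ_mean_true if is_true else config.occ_mean_decoy
            vals = np.clip(mean + rng.uniform(-0.05, 0.05,
                                              size=2 * _OCC_HALF + 1), 0, 1)
            vals = np.round(vals, 4)
            occ_means.append(float(
                vals[_OCC_HALF - 50:_OCC_HALF + 51].mean()))
            lo = center - _OCC_HALF
            fh.write("".join(
                f"{chrom}\t{lo + k}\t{lo + k + 1}\t{vals[k]:.4f}\n"
                for k in range(vals.shape[0])))

    # one gene TSS within 1 kb of each site
    genes: list[GeneRecord] = []
    sens_flags = []
    for site_id, chrom, center, is_true in sites:
        tss = center + int(rng.integers(-800, 801))
        strand = "+" if rng.random() < 0.5 else "-"
        p = (config.p_sensitive_gene_true if is_true
             else config.p_sensitive_gene_decoy)
        sensitive = bool(rng.random() < p)
        sens_flags.append(sensitive)
        genes.append(GeneRecord(gene_id=f"g_{site_id}", chrom=chrom,
                                tss=tss, strand=strand, sensitive=sensitive))
    paths["genes"] = outdir / "genes.tsv"
    write_genes(genes, paths["genes"])
    paths["sensitive_genes"] = outdir / "sensitive_genes.txt"
    with open(paths["sensitive_genes"], "w") as fh:
        for g in genes:
            if g.sensitive:
                fh.write(g.gene_id + "\n")

    # labeled positives: a random draw of true sites (qPCR-validated stand-in)
    true_idx = [k for k, s in enumerate(sites) if s[3]]
    if config.n_labeled_pos > len(true_idx):
        raise ValueError("n_labeled_pos exceeds number of true sites")
    chosen = np.sort(rng.choice(len(true_idx), size=config.n_labeled_pos,
                                replace=False))
    labeled_idx = {true_idx[c] for c in chosen}
    pos_peaks = [Peak(id=f"pos_{sites[k][0]}", chrom=sites[k][1],
                      start=sites[k][2] - _SITE_HALF,
                      end=sites[k][2] + _SITE_HALF, summit=sites[k][2],
                      score=1.0, source="validated")
                 for k in sorted(labeled_idx)]
    paths["labeled_positives"] = outdir / "labeled_positives.bed"
    write_peaks(pos_peaks, paths["labeled_positives"])

    # IgG-like negative pool: intervals >= 2 kb from every site center
    neg_peaks = _draw_negative_pool(rng, config, chroms, centers)
    paths["negative_pool"] = outdir / "negative_pool.bed"
    write_peaks(neg_peaks, paths["negative_pool"])

    truth = pd.DataFrame({
        "site_id": [s[0] for s in sites],
        "chrom": [s[1] for s in sites],
        "center": [s[2] for s in sites],
        "is_true": [int(s[3]) for s in sites],
        "motif_planted": [int(v) for v in planted],
        "er_overlap": [int(v) for v in er_flags],
        "occ_window_mean": occ_means,
        "sensitive_gene": [int(v) for v in sens_flags],
        "labeled_positive": [int(k in labeled_idx)
                             for k in range(n_sites)],
    })
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)

    _check_informative_margins(truth)

    manifest = {
        "config": asdict(config),
        "files": {k: str(v.name) for k, v in paths.items()},
        "sha256": {k: _sha256(v) for k, v in sorted(paths.items())},
        "n_sites": n_sites,
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return SyntheticDataset(config=config, outdir=outdir, paths=paths,
                            truth=truth)


def _draw_negative_pool(rng, config: SynthConfig, chroms,
                        centers) -> list[Peak]:
    """Sample interval midpoints uniformly over the region >= 2 kb from
    every site center (exact segment sampling, no rejection loop)."""
    segments = []       # (chrom, lo, hi) eligible midpoint ranges
    for chrom in chroms:
        lo = _EDGE_MARGIN
        for center in centers[chrom]:
            hi = center - _MIN_GAP
            if hi > lo:
                segments.append((chrom, lo, hi))
            lo = max(lo, center + _MIN_GAP)
        hi = config.genome_length - _EDGE_MARGIN
        if hi > lo:
            segments.append((chrom, lo, hi))
    lengths = np.array([hi - lo for _, lo, hi in segments], dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("no genomic space >= 2 kb away from all sites")
    cum = np.cumsum(lengths)
    draws = np.sort(rng.uniform(0.0, cum[-1], size=config.n_negative_pool))
    peaks = []
    for i, d in enumerate(draws):
        seg = int(np.searchsorted(cum, d, side="right"))
        chrom, lo, hi = segments[seg]
        mid = lo + int(d - (cum[seg] - lengths[seg]))
        mid = min(mid, hi - 1)
        peaks.append(Peak(id=f"neg_{i:04d}", chrom=chrom,
                          start=mid - _SITE_HALF, end=mid + _SITE_HALF,
                          summit=mid, score=0.0, source="igg"))
    return peaks


def _check_informative_margins(truth: pd.DataFrame,
                               min_margin: float = 0.2) -> None:
    """The non-trigram bits must each be marginally informative."""
    true = truth[truth.is_true == 1]
    decoy = truth[truth.is_true == 0]
    margins = {
        "occupancy": (true.occ_window_mean > 0.75).mean()
        - (decoy.occ_window_mean > 0.75).mean(),
        "er_overlap": true.er_overlap.mean() - decoy.er_overlap.mean(),
        "sensitive_gene": true.sensitive_gene.mean()
        - decoy.sensitive_gene.mean(),
    }
    for name, margin in margins.items():
        if margin <= min_margin:
            raise ValueError(
                f"generated data not informative: {name} margin "
                f"{margin:.3f} <= {min_margin}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def assign_candidates_to_sites(pool: CandidatePool,
                               truth: pd.DataFrame) -> dict[str, str]:
    """Map each merged candidate to the planted site whose center it spans."""
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, grp in truth.groupby("chrom"):
        grp = grp.sort_values("center")
        by_chrom[chrom] = (grp.center.to_numpy(), grp.site_id.tolist())
    mapping: dict[str, str] = {}
    for cand in pool.peaks:
        if cand.chrom not in by_chrom:
            continue
        centers, ids = by_chrom[cand.chrom]
        j = int(np.searchsorted(centers, cand.start, side="left"))
        if j < centers.shape[0] and cand.start <= centers[j] < cand.end:
            mapping[cand.id] = ids[j]
    return mapping


def ground_truth_metrics(predictions: dict[str, str],
                         truth: pd.DataFrame) -> tuple[float, float, float]:
    """Confusion-matrix metrics of site-level calls against generative labels.

    ``predictions`` maps site ids to "positive"/"negative"; every id must
    exist in the truth table. Metrics cover exactly the predicted sites
    (distinct from CV metrics, which use only the labeled subset).
    """
    is_true = dict(zip(truth.site_id, truth.is_true))
    tp = fp = tn = fn = 0
    for site_id, label in predictions.items():
        if site_id not in is_true:
            raise KeyError(f"unknown site id {site_id!r}")
        if is_true[site_id]:
            if label == "positive":
                tp += 1
            else:
                fn += 1
        elif label == "positive":
            fp += 1
        else:
            tn += 1
    return confusion_metrics(tp, fp, tn, fn)
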