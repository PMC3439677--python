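"""End-to-end orchestration: pool -> featurize -> classify -> evaluate.

``run_pipeline`` consumes a :class:`RunConfig` naming every input file,
executes the full workflow and writes four reports mirroring the study's
result tables: per-method ERE-containment (counts + 2 dp ratios), gene
mapping vs sensitive genes, cross-validated classifier metrics, and the
per-iteration self-training series. Ratios are stored at full precision and
rounded only in the human-readable reports; a JSON manifest records seeds
and input checksums so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import (POSITIVE, kmeans2, nb_classify_matrix, nb_fit,
                       rank_features_roc, sample_training, cross_validate)
from .features import FeatureConfig, build_feature_matrix, map_peak_to_gene
from .io_formats import (read_fasta, read_genes, read_occupancy, read_peaks,
                         write_classified_peaks)
from .motif_eval import PWM, contains_motif, default_ere_pwm
from .peak_pool import union_peaks
from .selftrain import evaluate_history, self_train

log = logging.getLogger("copeak")


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    caller_files: list[str]
    caller_names: list[str]
    genome: str
    occupancy: str
    er_peaks: str
    genes: str
    labeled_positives: str
    negative_pool: str
    outdir: str
    dialect: str = "bed6+summit"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    nb_threshold: float = 0.8
    ratio: int = 2
    selftrain_m: int = 5
    selftrain_max_iter: int = 75
    kmeans_restarts: int = 10
    cv_folds: int = 9
    seed: int = 0
    motif_flank: int = 300

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        fc = payload.pop("feature_config", None)
        cfg = cls(**payload)
        if fc:
            cfg.feature_config = FeatureConfig(**fc)
        return cfg


def _fmt_ratio(r: float) -> str:
    return "nan" if np.isnan(r) else f"{r:.2f}"


def run_pipeline(config: RunConfig, pwm: PWM | None = None) -> dict:
    """Run the full workflow; returns a results dict and writes reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pwm = pwm or default_ere_pwm()
    results: dict = {}

    log.info("stage pool: reading %d caller files", len(config.caller_files))
    peak_sets = [read_peaks(path, name, config.dialect)
                 for path, name in zip(config.caller_files,
                                       config.caller_names)]
    pool = union_peaks(peak_sets)
    results["n_candidates"] = len(pool)

    log.info("stage featurize: %d candidates", len(pool))
    genome = read_fasta(config.genome)
    track = read_occupancy(config.occupancy, genome=genome)
    er_peaks = read_peaks(config.er_peaks, "er", config.dialect)
    genes = read_genes(config.genes)
    fc = config.feature_config
    cand_ids, X = build_feature_matrix(pool, genome, track, er_peaks, genes,
                                       fc)

    pos_peaks = read_peaks(config.labeled_positives, "validated",
                           config.dialect)
    neg_peaks = read_peaks(config.negative_pool, "igg", config.dialect)
    pos_ids, pos_X = _featurize(pos_peaks, genome, track, er_peaks, genes, fc)
    neg_ids, neg_X = _featurize(neg_peaks, genome, track, er_peaks, genes, fc)

    log.info("stage train: NB, ratio 1:%d, threshold %.2f", config.ratio,
             config.nb_threshold)
    train = sample_training(pos_X, pos_ids, neg_X, neg_ids,
                            ratio=config.ratio, seed=config.seed)
    model = nb_fit(train, threshold=config.nb_threshold)
    model.to_json(outdir / "nb_model.json")

    labels, posteriors = nb_classify_matrix(model, X)
    write_classified_peaks(pool.peaks, labels, posteriors,
                           outdir / "classified_peaks.tsv")

    # motif containment per candidate, computed once and reused everywhere
    log.info("stage motif-eval: scanning %d windows", len(pool))
    has_motif = {p.id: contains_motif(p, genome, pwm,
                                      flank=config.motif_flank)
                 for p in pool.peaks}

    def set_ratio(ids: list[str]) -> tuple[int, int, float]:
        n = len(ids)
        k = sum(has_motif[i] for i in ids)
        return n, k, (k / n if n else float("nan"))

    log.info("stage cluster: k-means k=2, city-block")
    clusters = kmeans2(X, seed=config.seed + 1,
                       restarts=config.kmeans_restarts)

    log.info("stage selftrain: m=%d, max_iter=%d", config.selftrain_m,
             config.selftrain_max_iter)
    st = self_train(pos_X, pos_ids, neg_X, neg_ids, X, cand_ids,
                    m=config.selftrain_m,
                    max_iter=config.selftrain_max_iter,
                    threshold=config.nb_threshold, seed=config.seed + 2)
    st_series = evaluate_history(st.history, lambda ids: set_ratio(ids)[2])
    # the last history record scores the remaining unlabeled pool with the
    # final classifier, so its positive_ids are the final positive calls
    st_positive = list(st.history[-1].positive_ids)

    # Table-2-style report: per method, n peaks / n with ERE / ratio
    pos_set = [i for i, lab in zip(cand_ids, labels) if lab == POSITIVE]
    neg_set = [i for i, lab in zip(cand_ids, labels) if lab != POSITIVE]
    cluster_sets = {
        k: [cand_ids[j] for j in np.flatnonzero(clusters.assignment == k)]
        for k in (1, 2)}
    table2_rows = []
    for name, ids in [
        *((f"caller:{n}", None) for n in config.caller_names),
        ("kmeans cluster 1", cluster_sets[1]),
        ("kmeans cluster 2", cluster_sets[2]),
        (f"supervised-NB(th={config.nb_threshold:g},1:{config.ratio}) "
         "positive", pos_set),
        (f"supervised-NB(th={config.nb_threshold:g},1:{config.ratio}) "
         "negative", neg_set),
        (f"semi-supervised-NB(m={config.selftrain_m}) positive", st_positive),
    ]:
        if ids is None:     # per-caller rows use that caller's own peaks
            caller = name.split(":", 1)[1]
            caller_peaks = peak_sets[config.caller_names.index(caller)]
            n = len(caller_peaks)
            k = sum(contains_motif(p, genome, pwm, flank=config.motif_flank)
                    for p in caller_peaks)
            row = (name, n, k, k / n if n else float("nan"))
        else:
            n, k, r = set_ratio(ids)
            row = (name, n, k, r)
        table2_rows.append(row)
    _write_table(outdir / "report_ere_ratio.tsv",
                 ["method", "n_peaks", "n_with_ere", "ratio"],
                 [(m, n, k, _fmt_ratio(r)) for m, n, k, r in table2_rows])
    results["ere_table"] = table2_rows

    # Table-3-style report: gene mapping and sensitive-gene intersection
    peak_by_id = {p.id: p for p in pool.peaks}
    sensitive_ids = {g.gene_id for g in genes if g.sensitive}
    table3_rows = []
    for name, ids in [("pool", cand_ids), ("NB positive", pos_set)]:
        mapped = {map_peak_to_gene(peak_by_id[i], genes,
                                   fc.gene_max_distance) for i in ids}
        mapped_ids = {g.gene_id for g in mapped if g is not None}
        table3_rows.append((name, len(ids), len(mapped_ids),
                            len(mapped_ids & sensitive_ids)))
    _write_table(outdir / "report_gene_mapping.tsv",
                 ["method", "n_peaks", "n_genes_mapped",
                  "n_sensitive_genes"], table3_rows)
    results["gene_table"] = table3_rows

    # Table-4-style report: cross-validated classifier metrics
    precision, recall, accuracy = cross_validate(
        train, folds=config.cv_folds, threshold=config.nb_threshold,
        seed=config.seed + 3)
    _write_table(outdir / "report_cv.tsv",
                 ["classifier", "precision", "recall", "accuracy"],
                 [(f"NB(th={config.nb_threshold:g},1:{config.ratio})",
                   _fmt_ratio(precision), _fmt_ratio(recall),
                   _fmt_ratio(accuracy))])
    results["cv"] = (precision, recall, accuracy)

    _write_table(outdir / "report_selftrain_series.tsv",
                 ["iteration", "n_labeled", "n_promoted", "n_positive",
                  "ere_ratio", "empty"],
                 [(rec.t, rec.n_labeled, len(rec.promoted_ids), n, f"{r:.6f}",
                   int(flag))
                  for rec, (_, n, r, flag) in zip(st.history, st_series)])
    results["selftrain_series"] = st_series
    results["selftrain_stop_reason"] = st.stop_reason

    results["feature_ranking"] = rank_features_roc(train)
    results.update({
        "pool": pool, "candidate_ids": cand_ids, "features": X,
        "model": model, "labels": labels, "posteriors": posteriors,
        "has_motif": has_motif, "clusters": clusters, "train": train,
        "selftrain": st, "nb_positive_ids": pos_set,
        "nb_negative_ids": neg_set,
    })

    manifest = {
        "copeak_version": __version__,
        "seed": config.seed,
        "stage_seeds": {"train_sampling": config.seed,
                        "kmeans": config.seed + 1,
                        "selftrain": config.seed + 2,
                        "cv": config.seed + 3},
        "inputs_sha256": {
            name: _sha256(path) for name, path in sorted({
                **{n: f for n, f in zip(config.caller_names,
                                        config.caller_files)},
                "genome": config.genome, "occupancy": config.occupancy,
                "er_peaks": config.er_peaks, "genes": config.genes,
                "labeled_positives": config.labeled_positives,
                "negative_pool": config.negative_pool}.items())},
        "n_candidates": len(pool),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results


def _featurize(peaks, genome, track, er_peaks, genes, fc):
    ids, X = build_feature_matrix(peaks, genome, track, er_peaks, genes, fc)
    return ids, X


def _write_table(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
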