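"""End-to-end orchestration: features -> classification -> clustering -> scan.

``run_pipeline`` produces a deterministic report bundle in an output
directory: the feature matrix, derived statistics with labels, cluster
labels with silhouettes, group bookkeeping summaries, the genome-scan BED
and context summary, and a JSON run log recording the seed and the
thresholds actually used (preset or data-derived) so every classification
is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    PAPER_T_DHS_STRONG,
    PAPER_T_POLII,
    RodSignatureClassifier,
    round_half_away,
    summarize_groups,
)
from .cluster import average_linkage, between_set_sc, to_newick
from .features import build_feature_matrix
from .intervals import GenomicInterval, ValidationError
from .io import (
    ensure_dir,
    read_chrom_sizes,
    read_gene_models_gtf,
    read_track_bedgraph,
    read_tss_bed,
    write_bed,
)
from .scan import NearestCentroidSignature, scan_genome, summarize_contexts
from .simulate import SimResult

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    tss_bed: str | None = None
    gtf: str | None = None
    chrom_sizes: str | None = None
    track_dir: str | None = None
    outdir: str = "rodsig_out"
    seed: int = 0
    halfwidth: int = 1000
    threshold_preset: str = "data"   # "data" (mean + 2 SD) or "paper"
    k4_ratio_min: float = 3.0
    pseudocount: float = 1.0
    n_clusters: int = 2
    scale_features: bool = True
    scan: bool = True
    scan_path: str = "centroid"      # or "rule"
    scan_window: int = 2000
    scan_step: int = 500
    scan_max_gap: int = 0
    newick: bool = False


def _load_inputs(cfg: RunConfig):
    from .features import FEATURE_SPEC

    if not (cfg.tss_bed and cfg.chrom_sizes and cfg.track_dir):
        raise ValidationError("run_pipeline needs tss_bed, chrom_sizes and track_dir")
    tss = read_tss_bed(cfg.tss_bed)
    sizes = read_chrom_sizes(cfg.chrom_sizes)
    genes = read_gene_models_gtf(cfg.gtf) if cfg.gtf else []
    # explicit library sizes (sequencing depths) override the default
    # sum(score x length) mass when the track directory provides them
    lib_path = Path(cfg.track_dir) / "library_sizes.tsv"
    lib_sizes: dict[tuple[str, str], float] = {}
    if lib_path.exists():
        for line in lib_path.read_text().splitlines():
            if line.strip():
                a, tp, v = line.split("\t")
                lib_sizes[(a, tp)] = float(v)
    tracks = []
    for assay, tp, _ in FEATURE_SPEC:
        path = Path(cfg.track_dir) / f"{assay}_{tp}.bedGraph"
        if not path.exists():
            raise ValidationError(f"missing track file {path}")
        tracks.append(
            read_track_bedgraph(path, assay, tp,
                                library_size=lib_sizes.get((assay, tp)))
        )
    return tss, genes, sizes, tracks


def run_pipeline(cfg: RunConfig, sim: SimResult | None = None) -> dict:
    """Run every stage and write the report bundle; returns a summary dict.

    When ``sim`` is given its in-memory objects are used directly (the
    file-based inputs in ``cfg`` are ignored) and planted truth labels are
    attached to the outputs for comparison.
    """
    out = ensure_dir(cfg.outdir)
    stage = "load"
    try:
        if sim is not None:
            tss, genes, sizes, tracks = (
                sim.tss_records, sim.gene_models, sim.chrom_sizes, sim.tracks
            )
        else:
            tss, genes, sizes, tracks = _load_inputs(cfg)

        stage = "features"
        fm = build_feature_matrix(
            tss, tracks, halfwidth=cfg.halfwidth, chrom_sizes=sizes
        )
        fm.to_tsv(out / "features.tsv")

        stage = "classify"
        preset = cfg.threshold_preset
        clf = RodSignatureClassifier(
            k4_ratio_min=cfg.k4_ratio_min,
            pseudocount=cfg.pseudocount,
            t_polii=PAPER_T_POLII if preset == "paper" else None,
            t_dhs_strong=PAPER_T_DHS_STRONG if preset == "paper" else None,
        ).fit(fm)
        stats = clf.stats(fm)
        labels = clf.predict_from_stats(stats)
        stats = stats.copy()
        stats["label"] = labels
        stats["confidence"] = clf.confidence(fm)
        truth_labels = None
        if sim is not None:
            truth_labels = sim.truth_labels()
            stats["planted_class"] = truth_labels.reindex(stats.index).to_numpy()
        stats.to_csv(out / "derived.tsv", sep="\t", index_label="tss_id",
                     float_format="%.6g")

        stage = "cluster"
        res = average_linkage(
            fm.norm.to_numpy(), k=cfg.n_clusters, index=fm.norm.index,
            scale=cfg.scale_features,
        )
        cl = pd.DataFrame(
            {"cluster": res.labels, "silhouette": res.per_object_s}
        )
        cl.to_csv(out / "clusters.tsv", sep="\t", index_label="tss_id",
                  float_format="%.6g")
        if cfg.newick:
            (out / "dendrogram.nwk").write_text(
                to_newick(res.linkage_matrix, list(fm.norm.index))
            )

        stage = "summaries"
        summary = _group_summary(tss, stats, labels)
        summary.to_csv(out / "group_summary.tsv", sep="\t", index=False)

        hits = []
        context_summary = {}
        if cfg.scan:
            stage = "scan"
            centroid = None
            if cfg.scan_path == "centroid":
                centroid = NearestCentroidSignature().fit(fm.norm, labels)
            hits = scan_genome(
                tracks, sizes, classifier=clf, centroid_model=centroid,
                path=cfg.scan_path, window=cfg.scan_window, step=cfg.scan_step,
                max_gap=cfg.scan_max_gap, halfwidth=cfg.halfwidth,
                gene_models=genes, known_tss=tss,
            )
            scores = np.array([h.score for h in hits]) if hits else np.array([0.0])
            top = max(scores.max(), 1e-9)
            write_bed(
                [
                    GenomicInterval(h.interval.chrom, h.interval.start,
                                    h.interval.end,
                                    score=1000.0 * max(h.score, 0.0) / top)
                    for h in hits
                ],
                out / "scan_sites.bed",
            )
            pd.DataFrame(
                [
                    {"chrom": h.interval.chrom, "start": h.interval.start,
                     "end": h.interval.end, "score": round(h.score, 6),
                     "context": h.context, "nearest_gene": h.nearest_gene or "."}
                    for h in hits
                ],
                columns=["chrom", "start", "end", "score", "context", "nearest_gene"],
            ).to_csv(out / "scan_sites.tsv", sep="\t", index=False)
            if hits:
                context_summary = {
                    c: {"count": n, "percent": p}
                    for c, (n, p) in summarize_contexts(hits).items()
                }
            pd.DataFrame(
                [
                    {"context": c, "count": v["count"], "percent": v["percent"]}
                    for c, v in context_summary.items()
                ]
            ).to_csv(out / "context_summary.tsv", sep="\t", index=False)

        run_log = {
            "version": __version__,
            "seed": cfg.seed,
            "threshold_preset": preset,
            "t_polii": clf.t_polii_,
            "t_dhs_strong": clf.t_dhs_strong_,
            "k4_ratio_min": cfg.k4_ratio_min,
            "n_tss": len(tss),
            "n_scan_hits": len(hits),
            "average_silhouette": res.average_sc,
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
        return {
            "features": fm, "stats": stats, "cluster": res, "hits": hits,
            "classifier": clf, "summary": summary, "run_log": run_log,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _group_summary(tss, stats: pd.DataFrame, labels) -> pd.DataFrame:
    """Bookkeeping table in the style of the marker-by-marker counts."""
    df = stats.copy()
    df["label"] = labels
    n_in_gene = pd.Series(
        {t.tss_id: t.n_tss_in_gene for t in tss}, name="n_tss_in_gene"
    )
    df = df.join(n_in_gene)
    rows = []

    def add(population: str, sub: pd.DataFrame, mask, what: str) -> None:
        if len(sub) == 0:
            return
        count = int(mask.sum())
        rows.append(
            {"population": population, "n": len(sub), "feature": what,
             "count": count,
             "percent": round_half_away(100.0 * count / len(sub))}
        )

    pops = {
        "single-TSS rod": df[(df["n_tss_in_gene"] == 1) & (df["label"] == "rod")],
        "multi-TSS rod": df[(df["n_tss_in_gene"] > 1) & (df["label"] == "rod")],
        "multi-TSS common": df[(df["n_tss_in_gene"] > 1) & (df["label"] == "common")],
    }
    for name, sub in pops.items():
        add(name, sub, sub["crx_bound"], "CRX bound")
        add(name, sub, sub["nrl_bound"], "NRL bound")
        add(name, sub, sub["dhs_group"].isin(["up", "strong"]), "DHS increase")
        add(name, sub, sub["dhs_group"] == "down", "DHS decrease")
        add(name, sub, sub["polii_group"] != "none", "PolII increase")
        add(name, sub, sub["polii_group"] == "none", "PolII none")
    return pd.DataFrame(
        rows, columns=["population", "n", "feature", "count", "percent"]
    )


def worked_example_report(pairs: list[tuple[int, int]]) -> pd.DataFrame:
    """Percentages for (numerator, denominator) count pairs.

    Applies the same rounding as summarize_groups (half away from zero);
    a zero denominator is an error.
    """
    rows = []
    for num, den in pairs:
        if den == 0:
            raise ValidationError("zero denominator in worked example")
        labels = [1] * num + [0] * (den - num)
        count, pct = summarize_groups(labels, 1)
        rows.append({"numerator": num, "denominator": den, "percent": pct})
    return pd.DataFrame(rows)
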