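"""Genome-wide scan for loci bearing the rod-TSS chromatin signature.

The genome is tiled (default 2000 bp windows every 500 bp, matching the
±1000 bp feature window), the 13 features are computed at each tile
midpoint, and each tile is scored by one of two paths:

* ``rule`` — the tile passes iff the rule-based classifier calls it rod;
  the score is the number of satisfied signature criteria.
* ``centroid`` — nearest-centroid on the clustering geometry: tile features
  are standardized with the training moments and the tile passes iff its
  correlation distance to the rod class centroid is strictly smaller than
  to the common centroid; the score is that margin.

Tiles with no signal at all never pass, and neither does a tile with zero
DNase-hypersensitivity signal at every stage: open chromatin is a
precondition of the TSS-like signature, and windows that only catch the
read fringe of a neighbouring promoter lack it.  Passing tiles are merged into
sites and each site is annotated with one genomic context (promoter > TES >
exon > intron > intergenic precedence, decided at the site midpoint).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .classify import RodSignatureClassifier
from .cluster import corr_distance
from .features import FEATURE_COLUMNS, FeatureMatrix, build_feature_matrix
from .intervals import GeneModel, GenomicInterval, SignalTrack, TssRecord, ValidationError

CONTEXTS = ("promoter", "TES", "exon", "intron", "intergenic")


@dataclass
class ScanHit:
    """A merged genomic site passing the rod signature."""

    interval: GenomicInterval
    score: float
    context: str = "intergenic"
    nearest_gene: str | None = None


def tile_genome(
    chrom_sizes: dict[str, int], window: int = 2000, step: int = 500
) -> Iterator[GenomicInterval]:
    """Half-open tiles covering each chromosome; the last tile is clipped."""
    if not (window >= step > 0):
        raise ValidationError("need window >= step > 0")
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        last_start = max(length - window + step, 0)
        for start in range(0, last_start + 1, step):
            yield GenomicInterval(chrom, start, min(start + window, length))


class NearestCentroidSignature(ClassifierMixin, BaseEstimator):
    """Nearest-centroid classifier on the clustering geometry.

    ``fit`` standardizes the training features per column (sample SD) and
    stores the per-class mean of the standardized rows as centroids.
    ``predict`` standardizes new rows with the *training* moments and
    assigns the class whose centroid is closest in (1 - r)/2 correlation
    distance.  Rows that are all-zero in raw feature space are assigned
    the fallback class (no evidence is never a rod call).
    """

    def __init__(self, fallback: str = "common") -> None:
        self.fallback = fallback

    def fit(self, X, y) -> "NearestCentroidSignature":
        X = self._as_array(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValidationError("need at least 2 classes")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mean_) / self.scale_
        self.centroids_ = np.vstack(
            [Z[y == c].mean(axis=0) for c in self.classes_]
        )
        return self

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            return X.norm.to_numpy(dtype=float)
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def decision_function(self, X) -> np.ndarray:
        """Margin d(other) - d(rod-most class)… generically: per-class distances."""
        return self._distances(X)

    def _distances(self, X) -> np.ndarray:
        X = self._as_array(X)
        Z = (X - self.mean_) / self.scale_
        out = np.empty((X.shape[0], len(self.classes_)))
        for i, z in enumerate(Z):
            for j, c in enumerate(self.centroids_):
                out[i, j] = corr_distance(z, c)
        return out

    def predict(self, X) -> np.ndarray:
        arr = self._as_array(X)
        D = self._distances(X)
        fallback_j = int(np.where(self.classes_ == self.fallback)[0][0]) \
            if self.fallback in self.classes_ else 0
        labels = []
        for i in range(arr.shape[0]):
            if not arr[i].any():
                labels.append(self.classes_[fallback_j])
                continue
            j = int(np.argmin(D[i]))
            # strict-closeness rule: ties fall back
            if np.sum(D[i] == D[i, j]) > 1:
                j = fallback_j
            labels.append(self.classes_[j])
        return np.asarray(labels)


_DHS_IDX = [j for j, c in enumerate(FEATURE_COLUMNS) if c.startswith("DHS_")]


def _has_dhs_evidence(arr: np.ndarray) -> np.ndarray:
    """Open-chromatin gate: any nonzero DHS value across the three stages."""
    return arr[:, _DHS_IDX].any(axis=1)


def score_window(
    features: pd.Series | np.ndarray,
    classifier: RodSignatureClassifier | None = None,
    centroid_model: NearestCentroidSignature | None = None,
    path: str = "centroid",
) -> tuple[bool, float]:
    """Score one tile's 13-feature vector; returns (passes, score)."""
    vec = np.asarray(
        features[FEATURE_COLUMNS] if isinstance(features, pd.Series) else features,
        dtype=float,
    )
    if not vec.any() or not _has_dhs_evidence(vec[None, :])[0]:
        return False, 0.0
    frame = pd.DataFrame([vec], columns=FEATURE_COLUMNS, index=["tile"])
    if path == "rule":
        if classifier is None:
            raise ValidationError("rule path needs a fitted RodSignatureClassifier")
        fm = FeatureMatrix(frame, frame)
        stats = classifier.stats(fm)
        passes = classifier.predict_from_stats(stats)[0] == "rod"
        score = float(
            (stats["k4_ratio"].iloc[0] >= classifier.k4_ratio_min)
            + stats["k4_rd1_depleted"].iloc[0]
            + stats["dhs_group"].isin(["up", "strong"]).iloc[0]
            + stats["crx_bound"].iloc[0]
            + stats["nrl_bound"].iloc[0]
            + (stats["polii_group"].iloc[0] != "none")
        )
        return passes, score
    if path == "centroid":
        if centroid_model is None:
            raise ValidationError("centroid path needs a fitted NearestCentroidSignature")
        D = centroid_model._distances(frame)[0]
        j_rod = int(np.where(centroid_model.classes_ == "rod")[0][0])
        j_com = int(np.where(centroid_model.classes_ == "common")[0][0])
        score = float(D[j_com] - D[j_rod])
        return bool(D[j_rod] < D[j_com]), score
    raise ValidationError(f"unknown scoring path {path!r}")


def merge_hits(passing, max_gap: int = 0) -> list[ScanHit]:
    """Merge sorted passing tiles whose gap is <= max_gap; score = max."""
    items = sorted(passing, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: list[ScanHit] = []
    for interval, score in items:
        if out and out[-1].interval.chrom == interval.chrom and \
                interval.start - out[-1].interval.end <= max_gap:
            prev = out[-1]
            out[-1] = ScanHit(
                interval=GenomicInterval(
                    prev.interval.chrom, prev.interval.start,
                    max(prev.interval.end, interval.end),
                ),
                score=max(prev.score, score),
            )
        else:
            out.append(ScanHit(interval=interval, score=score))
    return out


def annotate_context(
    site: ScanHit | GenomicInterval,
    gene_models: list[GeneModel],
    known_tss: list[TssRecord],
    promoter_halfwidth: int = 1000,
    tes_halfwidth: int = 1000,
) -> tuple[str, str | None]:
    """(context, nearest_gene) for a site, decided at its midpoint.

    Precedence promoter > TES > exon > intron > intergenic; a promoter is
    any known TSS ± promoter_halfwidth, a TES region analogous.
    """
    interval = site.interval if isinstance(site, ScanHit) else site
    mid = interval.midpoint
    best_gene, best_dist = None, None
    for t in known_tss:
        if t.chrom != interval.chrom:
            continue
        d = abs(t.position - mid)
        if best_dist is None or d < best_dist:
            best_gene, best_dist = t.gene_id, d
        if t.position - promoter_halfwidth <= mid < t.position + promoter_halfwidth:
            return "promoter", t.gene_id
    hit_exon = hit_intron = None
    for g in gene_models:
        if g.chrom != interval.chrom:
            continue
        tes = g.tes_position
        if tes is not None and tes - tes_halfwidth <= mid < tes + tes_halfwidth:
            return "TES", g.gene_id
        if g.tx_start <= mid < g.tx_end:
            if any(s <= mid < e for s, e in g.exons):
                hit_exon = hit_exon or g.gene_id
            else:
                hit_intron = hit_intron or g.gene_id
    if hit_exon:
        return "exon", hit_exon
    if hit_intron:
        return "intron", hit_intron
    return "intergenic", best_gene


def summarize_contexts(hits: list[ScanHit]) -> dict[str, tuple[int, int]]:
    """Per-context (count, rounded percent); percentages sum to 100 ± 1."""
    from .classify import summarize_groups

    if not hits:
        raise ValidationError("no hits to summarize")
    labels = [h.context for h in hits]
    return {
        c: summarize_groups(labels, c) for c in CONTEXTS if c in labels
    }


def scan_genome(
    tracks: list[SignalTrack],
    chrom_sizes: dict[str, int],
    classifier: RodSignatureClassifier | None = None,
    centroid_model: NearestCentroidSignature | None = None,
    path: str = "centroid",
    window: int = 2000,
    step: int = 500,
    max_gap: int = 0,
    halfwidth: int = 1000,
    gene_models: list[GeneModel] | None = None,
    known_tss: list[TssRecord] | None = None,
) -> list[ScanHit]:
    """Tile the genome, score every tile, merge and annotate passing sites."""
    tiles = list(tile_genome(chrom_sizes, window=window, step=step))
    pseudo = [
        TssRecord(gene_id="tile", tss_id=f"tile_{i}", chrom=t.chrom,
                  position=t.midpoint)
        for i, t in enumerate(tiles)
    ]
    fm = build_feature_matrix(
        pseudo, tracks, halfwidth=halfwidth, chrom_sizes=chrom_sizes
    )
    passing: list[tuple[GenomicInterval, float]] = []
    if path == "centroid":
        if centroid_model is None:
            raise ValidationError("centroid path needs a fitted model")
        arr = fm.norm.to_numpy(dtype=float)
        nonzero = arr.any(axis=1) & _has_dhs_evidence(arr)
        D = centroid_model._distances(fm.norm[nonzero]) if nonzero.any() else None
        j_rod = int(np.where(centroid_model.classes_ == "rod")[0][0])
        j_com = int(np.where(centroid_model.classes_ == "common")[0][0])
        k = 0
        for i, tile in enumerate(tiles):
            if not nonzero[i]:
                continue
            d = D[k]; k += 1
            if d[j_rod] < d[j_com]:
                passing.append((tile, float(d[j_com] - d[j_rod])))
    else:
        if classifier is None:
            raise ValidationError("rule path needs a fitted classifier")
        stats = classifier.stats(fm)
        labels = classifier.predict_from_stats(stats)
        arr = fm.norm.to_numpy(dtype=float)
        nonzero = arr.any(axis=1) & _has_dhs_evidence(arr)
        scores = (
            (stats["k4_ratio"] >= classifier.k4_ratio_min).astype(float)
            + stats["k4_rd1_depleted"].astype(float)
            + stats["dhs_group"].isin(["up", "strong"]).astype(float)
            + stats["crx_bound"].astype(float)
            + stats["nrl_bound"].astype(float)
            + (stats["polii_group"] != "none").astype(float)
        ).to_numpy()
        for i, tile in enumerate(tiles):
            if nonzero[i] and labels[i] == "rod":
                passing.append((tile, float(scores[i])))
    hits = merge_hits(passing, max_gap=max_gap)
    if gene_models is not None or known_tss is not None:
        for h in hits:
            h.context, h.nearest_gene = annotate_context(
                h, gene_models or [], known_tss or []
            )
    return hits
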