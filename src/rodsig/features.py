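"""Window aggregation of signal tracks and assembly of the 13-feature matrix.

Each TSS is characterized in the symmetric window TSS ± 1000 bp by 13
chromatin features: H3K4me2 at five stages (E17, PN1, PN7, PN15 and the
rod-less RD1 mutant at PN30), DNase hypersensitivity at three stages
(1D, 1W, 8W), PolII occupancy at two (PN2, PN25), CRX binding in two ChIP
samples (S1, S2) and NRL binding (PN28).

Two aggregation modes exist because the source tracks differ in kind:

* ``count`` — read-derived tracks (H3K4me2, CRX, NRL, PolII): every track
  entry overlapping the window contributes its score once, regardless of
  how much of it lies inside (read-count semantics).
* ``weighted`` — the DHS score tracks: each entry contributes
  (bp of intersection with the window) × (entry score), so partial overlap
  contributes proportionally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, SignalTrack, TssRecord, ValidationError

DEFAULT_HALFWIDTH = 1000

#: the 13 features, in canonical column order, with their aggregation mode
FEATURE_SPEC: list[tuple[str, str, str]] = [
    ("H3K4me2", "E17", "count"),
    ("H3K4me2", "PN1", "count"),
    ("H3K4me2", "PN7", "count"),
    ("H3K4me2", "PN15", "count"),
    ("H3K4me2", "RD1", "count"),
    ("DHS", "1D", "weighted"),
    ("DHS", "1W", "weighted"),
    ("DHS", "8W", "weighted"),
    ("PolII", "PN2", "count"),
    ("PolII", "PN25", "count"),
    ("CRX", "S1", "count"),
    ("CRX", "S2", "count"),
    ("NRL", "PN28", "count"),
]

FEATURE_COLUMNS = [f"{a}_{t}" for a, t, _ in FEATURE_SPEC]
AGG_MODE = {f"{a}_{t}": m for a, t, m in FEATURE_SPEC}


def window_around_tss(
    tss: TssRecord,
    halfwidth: int = DEFAULT_HALFWIDTH,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomicInterval:
    """Symmetric window [position - halfwidth, position + halfwidth).

    Clipped at 0 and, when ``chrom_sizes`` is supplied, at the chromosome
    end; a position at or beyond the chromosome end is a validation error.
    """
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be positive")
    start = max(tss.position - halfwidth, 0)
    end = tss.position + halfwidth
    if chrom_sizes is not None:
        size = chrom_sizes.get(tss.chrom)
        if size is not None:
            if tss.position >= size:
                raise ValidationError(
                    f"TSS {tss.tss_id} position {tss.position} beyond end of "
                    f"{tss.chrom} ({size})"
                )
            end = min(end, size)
    return GenomicInterval(tss.chrom, start, end, strand=tss.strand)


def _candidates(track: SignalTrack, window: GenomicInterval):
    starts, ends, scores, maxlen = track.chrom_arrays(window.chrom)
    if len(starts) == 0:
        return None
    lo = np.searchsorted(starts, window.start - maxlen, side="left")
    hi = np.searchsorted(starts, window.end, side="left")
    if hi <= lo:
        return None
    s, e, v = starts[lo:hi], ends[lo:hi], scores[lo:hi]
    keep = e > window.start
    if not keep.any():
        return None
    return s[keep], e[keep], v[keep]


def aggregate_count(track: SignalTrack, window: GenomicInterval) -> float:
    """Sum of scores of entries overlapping the window (each counted once)."""
    cand = _candidates(track, window)
    if cand is None:
        return 0.0
    return float(cand[2].sum())


def aggregate_weighted(track: SignalTrack, window: GenomicInterval) -> float:
    """Sum over entries of (bp of intersection) x (entry score)."""
    cand = _candidates(track, window)
    if cand is None:
        return 0.0
    s, e, v = cand
    overlap = np.minimum(e, window.end) - np.maximum(s, window.start)
    return float((overlap * v).sum())


def normalize(value: float, library_size: float, scale: float = 1e6) -> float:
    """Counts-per-``scale`` normalization: value * scale / library_size."""
    if library_size <= 0:
        raise ValidationError("library_size must be positive")
    return value * scale / library_size


class FeatureMatrix:
    """Per-TSS feature values, raw and library-size normalized.

    Both tables are indexed by tss_id with the 13 canonical columns.
    When normalization is disabled the two tables are identical.
    """

    def __init__(self, raw: pd.DataFrame, norm: pd.DataFrame) -> None:
        if list(raw.columns) != FEATURE_COLUMNS or list(norm.columns) != FEATURE_COLUMNS:
            raise ValidationError("feature matrix must carry the 13 canonical columns")
        if (raw.to_numpy() < 0).any():
            raise ValidationError("raw features must be non-negative")
        self.raw = raw
        self.norm = norm

    def __len__(self) -> int:
        return len(self.raw)

    def to_tsv(self, path) -> None:
        out = self.raw.add_prefix("raw_").join(self.norm.add_prefix("norm_"))
        out.to_csv(path, sep="\t", index_label="tss_id", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="tss_id")
        raw = df[[f"raw_{c}" for c in FEATURE_COLUMNS]]
        raw.columns = FEATURE_COLUMNS
        norm = df[[f"norm_{c}" for c in FEATURE_COLUMNS]]
        norm.columns = FEATURE_COLUMNS
        return cls(raw, norm)


def build_feature_matrix(
    tss_list: list[TssRecord],
    tracks: list[SignalTrack],
    halfwidth: int = DEFAULT_HALFWIDTH,
    chrom_sizes: dict[str, int] | None = None,
    normalization: bool = True,
) -> FeatureMatrix:
    """Aggregate every required assay x timepoint track around every TSS.

    Exactly one track per (assay, timepoint) in the 13-feature list is
    required; a missing one raises a configuration error naming it.
    """
    by_key = {t.key: t for t in tracks}
    missing = [
        f"{a}@{tp}" for a, tp, _ in FEATURE_SPEC if (a, tp) not in by_key
    ]
    if missing:
        raise ValidationError(f"missing required tracks: {', '.join(missing)}")

    ids = [t.tss_id for t in tss_list]
    raw = np.zeros((len(tss_list), len(FEATURE_SPEC)))
    norm = np.zeros_like(raw)
    windows = [window_around_tss(t, halfwidth, chrom_sizes) for t in tss_list]
    for j, (assay, tp, mode) in enumerate(FEATURE_SPEC):
        track = by_key[(assay, tp)]
        agg = aggregate_weighted if mode == "weighted" else aggregate_count
        col = np.array([agg(track, w) for w in windows])
        raw[:, j] = col
        norm[:, j] = (
            col * 1e6 / track.library_size if normalization else col
        )
    return FeatureMatrix(
        pd.DataFrame(raw, index=pd.Index(ids, name="tss_id"), columns=FEATURE_COLUMNS),
        pd.DataFrame(norm, index=pd.Index(ids, name="tss_id"), columns=FEATURE_COLUMNS),
    )
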