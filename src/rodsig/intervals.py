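"""Domain types for the TSS chromatin-signature pipeline.

All coordinates are 0-based, half-open ``[start, end)`` internally, the BED
convention.  Strand is carried for reporting only: every aggregation window
is symmetric about the TSS, so strand never changes a computed feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

#: assays the pipeline knows about
ASSAYS = ("H3K4me2", "CRX", "NRL", "PolII", "DHS")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A scored, stranded genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")
        if self.score < 0:
            raise ValidationError("score must be non-negative")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TssRecord:
    """One annotated transcription start site with gene linkage.

    A gene with alternative TSS contributes several records sharing
    ``gene_id``.  ``known_class`` is a training label: ``rod`` for a
    cell-type-restricted (rod-photoreceptor) start, ``common`` for a
    constitutive start, ``unknown`` otherwise.
    """

    gene_id: str
    tss_id: str
    chrom: str
    position: int
    strand: str = "."
    n_tss_in_gene: int = 1
    known_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError("TSS position must be >= 0")
        if self.n_tss_in_gene < 1:
            raise ValidationError("n_tss_in_gene must be >= 1")
        if self.known_class not in ("unknown", "rod", "common"):
            raise ValidationError(f"bad known_class {self.known_class!r}")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")


class SignalTrack:
    """Scored genomic intervals for one assay at one timepoint.

    Intervals are held as a DataFrame sorted by (chrom, start) with columns
    chrom/start/end/score.  ``library_size`` is the total signal mass used
    for counts-per-million style normalization; by default it is
    sum(score * length) over all entries.

    Overlapping entries are retained as-is: the source tracks are read or
    peak files where each entry contributes independently.
    """

    def __init__(
        self,
        assay: str,
        timepoint: str,
        intervals: pd.DataFrame,
        library_size: float | None = None,
    ) -> None:
        if assay not in ASSAYS:
            raise ValidationError(f"unknown assay {assay!r}")
        required = {"chrom", "start", "end", "score"}
        if not required.issubset(intervals.columns):
            raise ValidationError(f"track needs columns {sorted(required)}")
        iv = intervals.loc[:, ["chrom", "start", "end", "score"]].copy()
        if len(iv) and (iv["score"] < 0).any():
            raise ValidationError("negative track scores")
        if len(iv) and (iv["end"] <= iv["start"]).any():
            raise ValidationError("zero/negative-length track entries")
        iv = iv.sort_values(["chrom", "start", "end"], kind="mergesort")
        iv = iv.reset_index(drop=True)
        self.assay = assay
        self.timepoint = timepoint
        self.intervals = iv
        if library_size is None:
            library_size = float(
                ((iv["end"] - iv["start"]) * iv["score"]).sum()
            )
        if library_size <= 0:
            # an all-empty track still needs a usable normalizer
            library_size = 1.0
        self.library_size = float(library_size)
        self._index: dict[str, tuple] = {}

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def key(self) -> tuple[str, str]:
        return (self.assay, self.timepoint)

    def chrom_arrays(self, chrom: str):
        """(starts, ends, scores, max_length) for one chromosome, cached."""
        hit = self._index.get(chrom)
        if hit is None:
            sub = self.intervals[self.intervals["chrom"] == chrom]
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            scores = sub["score"].to_numpy(dtype=np.float64)
            maxlen = int((ends - starts).max()) if len(starts) else 0
            hit = (starts, ends, scores, maxlen)
            self._index[chrom] = hit
        return hit


@dataclass
class GeneModel:
    """Minimal gene model: transcript span, exons, TSS/TES positions."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    tss_positions: list[int] = field(default_factory=list)
    tes_position: int | None = None

    def __post_init__(self) -> None:
        if self.tx_end <= self.tx_start:
            raise ValidationError("tx_end must exceed tx_start")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end:
                raise ValidationError("exon outside transcript span")
            if prev_end is not None and s < prev_end:
                raise ValidationError("overlapping exons")
            prev_end = e
        if self.tes_position is None:
            self.tes_position = (
                self.tx_start if self.strand == "-" else self.tx_end
            )
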