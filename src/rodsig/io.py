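"""Readers/writers for the standard text formats the pipeline touches.

BED6 for TSS and output sites, bedGraph (or scored BED) for signal tracks,
a minimal GTF for gene models and a two-column chrom.sizes TSV.  Everything
is 0-based half-open internally; GTF (1-based inclusive) is converted on
read.  Outputs are deterministic and UCSC-loadable.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .intervals import GeneModel, GenomicInterval, SignalTrack, TssRecord, ValidationError

log = logging.getLogger(__name__)

#: merge RefSeq isoform starts closer than this into one TSS record
TSS_COLLAPSE_BP = 50


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = path, lineno


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chrom<TAB>length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, lineno, "expected chrom<TAB>length")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad length {parts[1]!r}") from exc
    return sizes


def read_tss_bed(path, collapse_bp: int = TSS_COLLAPSE_BP) -> list[TssRecord]:
    """Read TSS annotations from BED6; name column encodes ``gene_id|tss_id``.

    Duplicate tss_id values are rejected.  Within a gene, TSS closer than
    ``collapse_bp`` are collapsed to the first record (single-bp RefSeq
    isoform starts would otherwise be double-counted); collapses are logged.
    """
    rows = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ParseError(path, lineno, f"expected >=6 BED fields, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            if "|" not in name:
                raise ParseError(path, lineno, "name must encode gene_id|tss_id")
            gene_id, tss_id = name.split("|", 1)
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(path, lineno, "non-integer coordinates") from exc
            if end_i <= start_i:
                raise ParseError(path, lineno, "end must exceed start")
            if tss_id in seen:
                raise ValidationError(f"duplicate tss_id {tss_id!r} at {path}:{lineno}")
            seen.add(tss_id)
            rows.append((gene_id, tss_id, chrom, start_i, strand))

    # collapse near-identical starts within a gene
    kept: list[tuple[str, str, str, int, str]] = []
    by_gene: dict[str, list[tuple[str, int]]] = {}
    for gene_id, tss_id, chrom, pos, strand in rows:
        close = [
            t for t, p in by_gene.get(gene_id, []) if abs(p - pos) < collapse_bp
        ]
        if close:
            log.info(
                "collapsing TSS %s into %s (<%d bp apart in gene %s)",
                tss_id, close[0], collapse_bp, gene_id,
            )
            continue
        by_gene.setdefault(gene_id, []).append((tss_id, pos))
        kept.append((gene_id, tss_id, chrom, pos, strand))

    n_per_gene = {g: len(v) for g, v in by_gene.items()}
    return [
        TssRecord(
            gene_id=g, tss_id=t, chrom=c, position=p, strand=s,
            n_tss_in_gene=n_per_gene[g],
        )
        for g, t, c, p, s in kept
    ]


def read_track_bedgraph(path, assay: str, timepoint: str,
                        library_size: float | None = None) -> SignalTrack:
    """Read a bedGraph (4-column) or scored BED into a SignalTrack.

    Unsorted input is sorted silently (logged); overlapping entries are kept
    as-is.  library_size defaults to sum(score * length).
    """
    chroms, starts, ends, scores = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError(path, lineno, f"expected >=4 columns, got {len(parts)}")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(path, lineno, "bad coordinates") from exc
            try:
                v = float(parts[3])
            except ValueError:
                # scored BED: column 4 is a name, the value sits in column 5
                if len(parts) < 5:
                    raise ParseError(path, lineno, "bad score column")
                try:
                    v = float(parts[4])
                except ValueError as exc:
                    raise ParseError(path, lineno, "bad score column") from exc
            if v < 0:
                raise ValidationError(f"negative score at {path}:{lineno}")
            chroms.append(parts[0]); starts.append(s); ends.append(e); scores.append(v)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "score": scores})
    if len(df) and not df[["chrom", "start"]].equals(
        df[["chrom", "start"]].sort_values(["chrom", "start"]).reset_index(drop=True)
    ):
        log.info("track %s was unsorted; sorting", path)
    return SignalTrack(assay, timepoint, df, library_size=library_size)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for row in track.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.score:g}\n")


def write_bed(sites: list[GenomicInterval], path) -> None:
    """Write BED6, ordered by (chrom, start); scores clipped to [0, 1000]."""
    ordered = sorted(sites, key=lambda s: (s.chrom, s.start, s.end))
    with open(path, "w") as fh:
        for i, s in enumerate(ordered, 1):
            score = int(round(min(max(s.score, 0.0), 1000.0)))
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tsite_{i}\t{score}\t{s.strand}\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(path, lineno, "expected >=3 BED fields")
            strand = parts[5] if len(parts) >= 6 else "."
            score = float(parts[4]) if len(parts) >= 5 else 0.0
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                       strand=strand, score=score))
    return out


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def write_gene_models_gtf(genes: list[GeneModel], path) -> None:
    """Minimal GTF: one transcript line and exon lines per gene (1-based)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\trodsig\ttranscript\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\trodsig\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gene_models_gtf(path) -> list[GeneModel]:
    """Parse transcript/exon GTF lines into GeneModel objects (0-based out)."""
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(path, lineno, "expected 9 GTF columns")
            chrom, _src, feature, start, end, _sc, strand, _fr, attr = parts[:9]
            attrs = dict(_GTF_ATTR.findall(attr))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(path, lineno, "missing gene_id attribute")
            rec = tx.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "start": None, "end": None, "exons": []},
            )
            s0, e0 = int(start) - 1, int(end)
            if feature == "transcript":
                rec["start"], rec["end"] = s0, e0
            elif feature == "exon":
                rec["exons"].append((s0, e0))
    genes = []
    for gene_id, rec in tx.items():
        start = rec["start"]
        end = rec["end"]
        if start is None:
            start = min(s for s, _ in rec["exons"])
            end = max(e for _, e in rec["exons"])
        genes.append(
            GeneModel(gene_id=gene_id, chrom=rec["chrom"], strand=rec["strand"],
                      tx_start=start, tx_end=end, exons=rec["exons"])
        )
    return genes


def write_tss_bed(records: list[TssRecord], path) -> None:
    ordered = sorted(records, key=lambda r: (r.chrom, r.position, r.tss_id))
    with open(path, "w") as fh:
        for r in ordered:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.gene_id}|{r.tss_id}\t0\t{r.strand}\n"
            )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
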