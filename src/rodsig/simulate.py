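"""Synthetic data with the statistical structure the pipeline assumes.

The generator lays out a small multi-chromosome genome of gene slots and
emits, for a configurable mix of single-TSS genes (all rod) and multi-TSS
genes (exactly one rod TSS, the rest common):

* a TSS BED and gene-model GTF,
* one bedGraph per assay x timepoint (13 tracks),
* a truth table with the planted class of every TSS and the interval and
  genomic context of every planted non-TSS rod-signature site.

Class-conditional laws: H3K4me2 developmental ratios are lognormal
(rod centered 10.1, common 2.6), with the RD1 rod-less control at the PN1
level for rod TSS and at the PN15 level for common TSS; CRX/NRL binding is
bimodal (exactly 0 when unbound, at least 300 reads when bound) with
class-dependent probabilities; DHS and PolII developmental groups are drawn
with the class proportions observed in the retina data; every read count is
negative-binomial noised and DHS scores carry lognormal noise.  Planted
sites copy the rod law at intronic/intergenic positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GeneModel, SignalTrack, TssRecord, ValidationError
from .io import (
    ensure_dir,
    write_bedgraph,
    write_gene_models_gtf,
    write_tss_bed,
)

# gene-slot layout constants (bp)
SLOT = 40_000           # one gene slot
GENE_OFFSET = 8_000     # gene start within its slot
GENE_LENGTH = 24_000
EXONS = ((0, 300), (14_000, 14_300), (23_700, 24_000))  # relative to gene start
ROD_TSS_OFFSET = 14_000     # internal alternative start (exon 2)
THIRD_TSS_OFFSET = 7_000    # second common start, intronic
INTRON_PLANT_OFFSET = 7_000
INTERGENIC_PLANT_OFFSET = 36_000  # relative to slot start, past the TES
CHROM_TAIL = 20_000


@dataclass
class SimConfig:
    """Generator conditions; defaults reproduce the study's cohort structure."""

    seed: int = 0
    n_genes_single: int = 72
    n_genes_two_tss: int = 27
    n_genes_three_tss: int = 8
    # H3K4me2 developmental ratio laws (PN15/PN1), lognormal mean/spread
    rod_k4_ratio: float = 10.1
    rod_k4_spread: float = 2.1
    common_k4_ratio: float = 2.6
    common_k4_spread: float = 0.5
    #: read the spread as SEM over the cohort instead of a per-TSS SD
    ratio_spread_is_sem: bool = False
    # bimodal TF binding
    p_crx_rod: float = 0.73
    p_crx_common: float = 0.08
    p_nrl_rod: float = 0.56
    p_nrl_common: float = 0.03
    bound_reads_min: int = 300
    bound_reads_extra_mean: float = 250.0
    # developmental group proportions (down/up/strong; none/low/high)
    dhs_groups_rod: tuple[float, float, float] = (0.06, 0.07, 0.87)
    dhs_groups_common: tuple[float, float, float] = (0.73, 0.16, 0.11)
    polii_groups_rod: tuple[float, float, float] = (0.33, 0.31, 0.36)
    polii_groups_common: tuple[float, float, float] = (0.76, 0.16, 0.08)
    # base signal levels and noise
    rod_k4_base: float = 50.0
    common_k4_base: float = 120.0
    polii_base: float = 40.0
    dhs_score_rod: float = 1.0
    dhs_score_common: float = 3.0
    nb_dispersion: float = 30.0     # negative-binomial size parameter
    dhs_noise_sd: float = 0.08      # lognormal sigma on DHS scores
    #: per-track sequencing-depth factors drawn uniformly from this range;
    #: library_size = depth x 1e6, so normalization must undo the depth
    depth_range: tuple[float, float] = (0.5, 2.0)
    # planted non-TSS rod-signature sites and genome shape
    n_planted_sites: int = 20
    n_chroms: int = 3

    def n_genes(self) -> int:
        return self.n_genes_single + self.n_genes_two_tss + self.n_genes_three_tss

    def n_tss(self) -> int:
        return (
            self.n_genes_single
            + 2 * self.n_genes_two_tss
            + 3 * self.n_genes_three_tss
        )


@dataclass
class SimResult:
    """In-memory bundle of one generator run."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    tss_records: list[TssRecord]
    gene_models: list[GeneModel]
    tracks: list[SignalTrack]
    truth: pd.DataFrame = field(repr=False)

    def truth_labels(self) -> pd.Series:
        t = self.truth[self.truth["record_type"] == "tss"]
        return pd.Series(t["label"].to_numpy(), index=t["id"].to_numpy())

    def truth_sites(self) -> pd.DataFrame:
        return self.truth[self.truth["record_type"] == "site"].reset_index(drop=True)

    def write(self, outdir) -> Path:
        out = ensure_dir(outdir)
        write_tss_bed(self.tss_records, out / "tss.bed")
        write_gene_models_gtf(self.gene_models, out / "genes.gtf")
        with open(out / "chrom.sizes", "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                fh.write(f"{chrom}\t{self.chrom_sizes[chrom]}\n")
        with open(out / "library_sizes.tsv", "w") as fh:
            for track in self.tracks:
                fh.write(f"{track.assay}\t{track.timepoint}\t{track.library_size:g}\n")
                write_bedgraph(track, out / f"{track.assay}_{track.timepoint}.bedGraph")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        return out


class _TrackBuilder:
    def __init__(self, depths: dict[tuple[str, str], float]) -> None:
        self.entries: dict[tuple[str, str], list[tuple[str, int, int, float]]] = {}
        self.depths = depths

    def add_reads(self, assay: str, tp: str, chrom: str, pos: int, count: int) -> None:
        """Deposit `count` reads as 4 fixed-offset 200 bp entries in pos±800."""
        count = int(round(count * self.depths.get((assay, tp), 1.0)))
        if count <= 0:
            return
        q, r = divmod(int(count), 4)
        scores = (q + r, q, q, q)
        for off, sc in zip((-700, -300, 100, 500), scores):
            if sc > 0:
                self.entries.setdefault((assay, tp), []).append(
                    (chrom, pos + off, pos + off + 200, float(sc))
                )

    def add_score(self, assay: str, tp: str, chrom: str, pos: int, score: float) -> None:
        """One 800 bp scored entry centred on pos (DHS-style track)."""
        score = score * self.depths.get((assay, tp), 1.0)
        if score > 0:
            self.entries.setdefault((assay, tp), []).append(
                (chrom, pos - 400, pos + 400, float(round(score, 4)))
            )

    def build(self) -> list[SignalTrack]:
        from .features import FEATURE_SPEC

        tracks = []
        for assay, tp, _ in FEATURE_SPEC:
            rows = self.entries.get((assay, tp), [])
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
            tracks.append(
                SignalTrack(
                    assay, tp, df,
                    library_size=self.depths.get((assay, tp), 1.0) * 1e6,
                )
            )
        return tracks


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, float(np.sqrt(sigma2))


def _nb(rng: np.random.Generator, mu: float, size_param: float) -> int:
    """Negative-binomial draw with mean mu and dispersion `size_param`."""
    if mu <= 0:
        return 0
    p = size_param / (size_param + mu)
    return int(rng.negative_binomial(size_param, p))


def _categorical(rng: np.random.Generator, probs) -> int:
    probs = np.asarray(probs, dtype=float)
    return int(rng.choice(len(probs), p=probs / probs.sum()))


def simulate(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Run the generator; same seed implies byte-identical written output."""
    cfg = config or SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    n_genes = cfg.n_genes()
    if n_genes < 1:
        raise ValidationError("need at least one gene")
    per_chrom = int(np.ceil(n_genes / cfg.n_chroms))
    chrom_sizes = {}
    slots: list[tuple[str, int]] = []  # (chrom, slot_start) per gene
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n_here = min(per_chrom, n_genes - len(slots))
        if n_here <= 0:
            break
        chrom_sizes[chrom] = n_here * SLOT + CHROM_TAIL
        for si in range(n_here):
            slots.append((chrom, si * SLOT))
    if cfg.n_planted_sites > 0 and cfg.n_genes_single < (cfg.n_planted_sites + 1) // 2:
        raise ValidationError("genome too small: not enough single-TSS gene "
                              "introns for the requested planted sites")

    gene_types = (
        ["single"] * cfg.n_genes_single
        + ["two"] * cfg.n_genes_two_tss
        + ["three"] * cfg.n_genes_three_tss
    )
    gene_types = [gene_types[i] for i in rng.permutation(n_genes)]

    # derive per-TSS lognormal dispersion for the ratio laws
    def ratio_law(mean: float, spread: float, n_class: int) -> tuple[float, float]:
        sd = spread * np.sqrt(max(n_class, 2)) if cfg.ratio_spread_is_sem else spread
        return _lognormal_params(mean, sd)

    n_rod = n_genes  # one rod TSS per gene
    n_common = cfg.n_tss() - n_rod
    rod_mu, rod_sigma = ratio_law(cfg.rod_k4_ratio, cfg.rod_k4_spread, n_rod)
    com_mu, com_sigma = ratio_law(
        cfg.common_k4_ratio, cfg.common_k4_spread, max(n_common, 2)
    )

    # sequencing-depth factors per track; the bimodal CRX/NRL tracks keep
    # depth 1 so the unbound-0 / bound->=300 gap survives verbatim
    from .features import FEATURE_SPEC

    lo, hi = cfg.depth_range
    depths = {
        (a, tp): (1.0 if a in ("CRX", "NRL") else float(rng.uniform(lo, hi)))
        for a, tp, _ in FEATURE_SPEC
    }
    tb = _TrackBuilder(depths)
    tss_records: list[TssRecord] = []
    gene_models: list[GeneModel] = []
    truth_rows: list[dict] = []

    def draw_dhs_ratio(group: int) -> float:
        if group == 0:      # down
            return float(rng.uniform(0.75, 0.98))
        if group == 1:      # up
            return float(rng.uniform(1.02, 1.33))
        mu, sg = _lognormal_params(2.5, 1.6)
        return 1.45 + float(rng.lognormal(mu, sg))

    def draw_bound_split(two_samples: bool) -> tuple[int, int]:
        total = cfg.bound_reads_min + _nb(rng, cfg.bound_reads_extra_mean, 5.0)
        if not two_samples:
            return total, 0
        s1 = int(rng.binomial(total, 0.5))
        return s1, total - s1

    def emit_profile(chrom: str, pos: int, klass: str, dhs_groups, polii_groups) -> None:
        """Draw one class-conditional 13-feature profile and deposit signal."""
        disp = cfg.nb_dispersion
        if klass == "rod":
            b = cfg.rod_k4_base
            r = float(rng.lognormal(rod_mu, rod_sigma))
            k4 = {
                "E17": _nb(rng, 0.8 * b, disp),
                "PN1": _nb(rng, b, disp),
                "PN7": _nb(rng, b * np.sqrt(r), disp),
                "PN15": _nb(rng, b * r, disp),
                "RD1": _nb(rng, b, disp),       # rod signal lost with the rods
            }
            p_crx, p_nrl = cfg.p_crx_rod, cfg.p_nrl_rod
            dhs_base = cfg.dhs_score_rod
        else:
            c = cfg.common_k4_base
            r = float(rng.lognormal(com_mu, com_sigma))
            k4 = {
                "E17": _nb(rng, c, disp),
                "PN1": _nb(rng, c, disp),
                "PN7": _nb(rng, c * np.sqrt(r), disp),
                "PN15": _nb(rng, c * r, disp),
                "RD1": _nb(rng, c * r, disp),   # unchanged without rods
            }
            p_crx, p_nrl = cfg.p_crx_common, cfg.p_nrl_common
            dhs_base = cfg.dhs_score_common
        for tp, count in k4.items():
            tb.add_reads("H3K4me2", tp, chrom, pos, count)

        # DHS: developmental ratio by planted group, lognormal score noise
        g = _categorical(rng, dhs_groups)
        ratio = draw_dhs_ratio(g)
        noise = lambda: float(rng.lognormal(-cfg.dhs_noise_sd ** 2 / 2, cfg.dhs_noise_sd))
        s1 = dhs_base * noise()
        tb.add_score("DHS", "1D", chrom, pos, s1)
        tb.add_score("DHS", "1W", chrom, pos, dhs_base * np.sqrt(ratio) * noise())
        tb.add_score("DHS", "8W", chrom, pos, dhs_base * ratio * noise())

        # PolII: delta by planted group
        g = _categorical(rng, polii_groups)
        base = cfg.polii_base
        if g == 0:
            pn25_mu = base * rng.uniform(0.5, 1.0)
        elif g == 1:
            pn25_mu = base + rng.uniform(10.0, 120.0)
        else:
            pn25_mu = base + rng.uniform(220.0, 500.0)
        tb.add_reads("PolII", "PN2", chrom, pos, _nb(rng, base, disp))
        tb.add_reads("PolII", "PN25", chrom, pos, _nb(rng, pn25_mu, disp))

        # bimodal TF binding
        if rng.random() < p_crx:
            s1c, s2c = draw_bound_split(two_samples=True)
            tb.add_reads("CRX", "S1", chrom, pos, s1c)
            tb.add_reads("CRX", "S2", chrom, pos, s2c)
        if rng.random() < p_nrl:
            total, _ = draw_bound_split(two_samples=False)
            tb.add_reads("NRL", "PN28", chrom, pos, total)

    # --- genes and their TSS ---------------------------------------------
    for gi, ((chrom, slot_start), gtype) in enumerate(zip(slots, gene_types)):
        g0 = slot_start + GENE_OFFSET
        gene_id = f"gene{gi + 1:04d}"
        exons = [(g0 + s, g0 + e) for s, e in EXONS]
        gene_models.append(
            GeneModel(gene_id=gene_id, chrom=chrom, strand="+",
                      tx_start=g0, tx_end=g0 + GENE_LENGTH, exons=exons)
        )
        if gtype == "single":
            tss_pos = {"T1": (g0, "rod")}
        elif gtype == "two":
            tss_pos = {"T1": (g0, "common"), "T2": (g0 + ROD_TSS_OFFSET, "rod")}
        else:
            tss_pos = {
                "T1": (g0, "common"),
                "T2": (g0 + ROD_TSS_OFFSET, "rod"),
                "T3": (g0 + THIRD_TSS_OFFSET, "common"),
            }
        n_in_gene = len(tss_pos)
        for tname, (pos, klass) in tss_pos.items():
            tss_id = f"{gene_id}.{tname}"
            tss_records.append(
                TssRecord(gene_id=gene_id, tss_id=tss_id, chrom=chrom,
                          position=pos, strand="+", n_tss_in_gene=n_in_gene,
                          known_class=klass)
            )
            truth_rows.append(
                {"record_type": "tss", "id": tss_id, "chrom": chrom,
                 "start": pos, "end": pos + 1, "label": klass}
            )
            groups = (
                (cfg.dhs_groups_rod, cfg.polii_groups_rod)
                if klass == "rod"
                else (cfg.dhs_groups_common, cfg.polii_groups_common)
            )
            emit_profile(chrom, pos, klass, *groups)

    # --- planted non-TSS rod-signature sites ------------------------------
    n_intronic = cfg.n_planted_sites // 2
    n_intergenic = cfg.n_planted_sites - n_intronic
    single_idx = [i for i, t in enumerate(gene_types) if t == "single"]
    intron_hosts = sorted(rng.choice(single_idx, size=n_intronic, replace=False)) \
        if n_intronic else []
    inter_hosts = sorted(rng.choice(n_genes, size=n_intergenic, replace=False)) \
        if n_intergenic else []
    plant_no = 0
    for host, context in [(i, "intron") for i in intron_hosts] + \
                         [(i, "intergenic") for i in inter_hosts]:
        chrom, slot_start = slots[host]
        if context == "intron":
            pos = slot_start + GENE_OFFSET + INTRON_PLANT_OFFSET
        else:
            pos = slot_start + INTERGENIC_PLANT_OFFSET
        plant_no += 1
        site_id = f"planted{plant_no:02d}"
        truth_rows.append(
            {"record_type": "site", "id": site_id, "chrom": chrom,
             "start": pos - 1000, "end": pos + 1000, "label": context}
        )
        emit_profile(chrom, pos, "rod", cfg.dhs_groups_rod, cfg.polii_groups_rod)

    truth = pd.DataFrame(
        truth_rows, columns=["record_type", "id", "chrom", "start", "end", "label"]
    )
    return SimResult(
        config=cfg,
        chrom_sizes=chrom_sizes,
        tss_records=tss_records,
        gene_models=gene_models,
        tracks=tb.build(),
        truth=truth,
    )


def truth_compare_labels(predicted: pd.Series, truth_labels: pd.Series,
                         positive: str = "rod") -> dict[str, float]:
    """Accuracy, recall and false-discovery fraction for class labels."""
    pred = pd.Series(predicted)
    unknown = set(pred.index) - set(truth_labels.index)
    if unknown:
        raise ValidationError(f"unknown ids in predictions: {sorted(unknown)[:5]}")
    truth = truth_labels.loc[pred.index]
    acc = float((pred == truth).mean())
    pos_truth = truth == positive
    recall = float((pred[pos_truth] == positive).mean()) if pos_truth.any() else 1.0
    called = pred == positive
    fdr = float((truth[called] != positive).mean()) if called.any() else 0.0
    return {"accuracy": acc, "recall": recall, "fdr": fdr}


def truth_compare_sites(hits, truth_sites: pd.DataFrame,
                        exclude_windows=None) -> dict[str, float]:
    """Site recovery metrics by >= 1 bp overlap.

    ``exclude_windows`` (e.g. known rod-TSS promoter windows) removes hits
    from the false-discovery accounting: the scan legitimately re-finds
    training TSS, which are neither planted nor false.
    """
    from .scan import ScanHit

    intervals = [h.interval if isinstance(h, ScanHit) else h for h in hits]

    def overlaps_row(iv, row) -> bool:
        return iv.chrom == row.chrom and iv.start < row.end and row.start < iv.end

    recovered = 0
    for row in truth_sites.itertuples(index=False):
        if any(overlaps_row(iv, row) for iv in intervals):
            recovered += 1
    recall = recovered / len(truth_sites) if len(truth_sites) else 1.0

    def excluded(iv) -> bool:
        return exclude_windows is not None and any(
            iv.overlaps(w) for w in exclude_windows
        )

    considered = [iv for iv in intervals if not excluded(iv)]
    unplanted = [
        iv for iv in considered
        if not any(overlaps_row(iv, row) for row in truth_sites.itertuples(index=False))
    ]
    fdr = len(unplanted) / len(considered) if considered else 0.0
    return {
        "recall": float(recall),
        "fdr": float(fdr),
        "n_hits": float(len(intervals)),
        "n_considered": float(len(considered)),
    }
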