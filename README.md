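# rodsig

Chromatin-signature classification of alternative transcription start
sites (TSS).

Many genes expressed across tissues carry several TSS, and which start is
used can be cell-type specific. In the developing mouse retina,
rod-photoreceptor-restricted starts ("rod TSS") carry a recognizable
epigenomic signature that constitutive starts ("common TSS") lack:
H3K4me2 accumulates strongly during development (PN15/PN1 ratio near 10
versus near 2.6 at common starts) and is lost in the rod-less RD1 mutant,
a DNase-hypersensitive site appears postnatally (DHS 8W/1D), PolII binding
rises (ΔPolII = PN25 − PN2), and the rod transcription factors CRX and NRL
bind nearby in a bimodal all-or-nothing fashion. `rodsig` implements this
classification scheme for anyone who wants to call cell-type-restricted
alternative promoters from multi-timepoint interval tracks:

* **feature extraction** — 13 chromatin features per TSS, aggregated in the
  symmetric window TSS ± 1000 bp (read-count semantics for ChIP tracks,
  bp-overlap × score for DHS);
* **classification** — derived statistics, data-derived thresholds
  (mean + 2 SD, with the original retina analysis values 182 / 1.35 available as presets),
  and a rule-based rod/common call (`RodSignatureClassifier`, a
  scikit-learn-style estimator);
* **validation** — average-linkage hierarchical clustering on the
  (1 − r)/2 correlation distance of z-scaled features, with silhouette
  coefficients s = (B − A)/max(A, B) per object and on average;
* **genome scan** — tiling scan for unannotated loci bearing the rod
  signature (nearest-centroid or rule scoring), merged into sites and
  annotated with genomic context (promoter / TES / exon / intron /
  intergenic);
* **synthetic data** — a generator that emulates the statistical structure
  of the real tracks with planted ground truth, so the whole pipeline runs
  and is tested without any downloads.

Inputs are plain text: BED6 TSS annotations, bedGraph signal tracks, a
minimal GTF for gene models and a two-column chrom.sizes file. All
coordinates are 0-based half-open; outputs are UCSC-loadable.

## Worked example

Generate a synthetic cohort with the default structure (72 single-TSS
genes, 27 with two TSS, 8 with three — 150 TSS, one rod TSS per gene — and
20 planted non-TSS rod-signature sites), then run the full pipeline:

```sh
rodsig simulate --seed 1 --outdir demo/sim
rodsig all --tss demo/sim/tss.bed --gtf demo/sim/genes.gtf \
    --tracks demo/sim --chrom-sizes demo/sim/chrom.sizes \
    --outdir demo/run --seed 1
```

which prints

```
wrote 150 TSS, 13 tracks to demo/sim
done: 150 TSS, 127 scan hits, average SC 0.526
```

The average silhouette of 0.526 for the 2-cluster TSS partition is above
the 0.5 bar for a reasonable partition, i.e. the rod/common split is a real
cluster structure. `demo/run/derived.tsv` holds the per-TSS statistics and
calls:

```
tss_id       k4_ratio  k4_rd1_depleted  delta_polii  dhs_ratio  crx_reads  nrl_reads  crx_bound  nrl_bound  polii_group  dhs_group  label  confidence
gene0001.T1  9.46829   True             -9.73764     3.32649    592        416        True       True       none         up         rod    0.666667
gene0002.T1  9.30733   True             331.956      3.16046    0          0          False      False      low          up         rod    0.333333
```

`gene0001.T1` shows the full signature (10-fold H3K4me2 gain, RD1
depletion, developmental DHS gain, CRX and NRL bound) and is called rod
with high confidence; `gene0002.T1` lacks TF binding — which a sizeable
minority of genuine rod TSS do — and is still called rod, at lower
confidence. The scan's merged sites land where they should
(`demo/run/context_summary.tsv`):

```
context     count  percent
promoter    107    84
intron      10     8
intergenic  10     8
```

107 promoter sites are the rod TSS themselves re-found by the scan
(self-consistency); the 10 intronic and 10 intergenic sites are exactly the
20 planted non-TSS signature loci. `run_log.json` records the seed and the
thresholds actually used, so every call is auditable.

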