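# Methods

## The classification problem

A gene with alternative transcription start sites can drive one transcript
constitutively and another in a single cell type. The package decides, per
annotated TSS, whether its chromatin environment looks like a
developmentally activated, rod-photoreceptor-restricted start ("rod") or a
constitutive start ("common"), using 13 features measured in the symmetric
window TSS ± 1000 bp:

| assay | timepoints | aggregation |
|---|---|---|
| H3K4me2 | E17, PN1, PN7, PN15, RD1 (PN30, rod-less mutant) | count |
| DHS | 1D, 1W, 8W | bp-overlap × score |
| PolII | PN2, PN25 | count |
| CRX | samples S1, S2 | count |
| NRL | PN28 | count |

`count` sums the scores of all track entries overlapping the window, each
entry once however partially it overlaps (read-count semantics for tracks
whose entries represent reads or read clusters). `weighted` multiplies each
entry's score by the bp of intersection, so partial overlap contributes
proportionally (appropriate for DHS score tracks whose entries are broad
scored regions). Windows are symmetric about the TSS, so strand never
affects a feature and is carried for reporting only. Coordinates are
0-based half-open throughout; overlapping track entries are kept as-is and
all contribute.

## Normalization

Counts are converted to counts-per-million using each track's
`library_size` (total sequencing/score mass). For real data the library
size defaults to Σ(score × length) over the track; tracks that represent
only a small slice of a genome should supply explicit library sizes (the
pipeline reads a `library_sizes.tsv` next to the bedGraphs when present),
because a signal-dominated mass estimate would cancel the very
developmental changes being measured. Normalization can be switched off
for pre-normalized tracks. Cross-timepoint ratios and ΔPolII are computed
on normalized values; the bimodal binding calls use raw counts (zero is
preserved by normalization, so the calls are insensitive to the choice).

## Derived statistics and thresholds

* `k4_ratio` = (H3K4me2 PN15 + c) / (PN1 + c), pseudocount c = 1 so
  zero-coverage windows stay defined; `k4_rd1_depleted` = RD1 < PN15.
* `delta_polii` = PolII PN25 − PN2, partitioned as
  delta ≤ 0 → `none`, 0 < delta ≤ t → `low`, delta > t → `high`.
* `dhs_ratio` = (DHS 8W + c)/(1D + c), partitioned as ratio < 1 → `down`,
  1 ≤ ratio ≤ t → `up`, ratio > t → `strong`.
* binding calls: 0 reads = unbound, anything positive = bound (CRX S1 and
  S2 stay separate features for clustering but are summed for the call).

The two data-dependent cuts default to mean + 2 sample SD — over the
positive PolII deltas and over the DHS ratios of the fitted TSS set
respectively — mirroring how the original retina values (182 and 1.35)
were obtained; those two values are available as fixed presets
(`threshold_preset="paper"`). Boundary values go to the lower group in
both partitions so that every real input lands in exactly one group.
Which TSS population the original cuts were computed over is not
documented, which is why both recomputation and presets exist.

The rule-based call labels a TSS rod iff `k4_ratio` ≥ 3.0 (a gate placed
between the common cohort mean of 2.6 and the rod mean of 10.1,
configurable), RD1 is depleted, and the DHS group is `up` or `strong`.
CRX/NRL binding and PolII up-regulation are *supporting* marks: roughly a
quarter of genuine rod TSS lack CRX and nearly half lack NRL, so requiring
them would be wrong; they feed a 0–1 confidence score instead.

Percentages in all bookkeeping tables round to the nearest integer, halves
away from zero — the convention that reproduces every percentage printed
in the original tallies.

## Cluster validation

Features are z-scaled per column (sample SD; constant columns map to
zeros) before clustering — on raw counts the largest-magnitude assay would
dominate — and scaling can be switched off. Dissimilarity is
(1 − Pearson r)/2; a zero-variance vector gets r := 0, distance 0.5, by
convention. Agglomeration is unweighted average linkage (scipy), cut at
k = 2 for the rod/common partition; labels are renumbered by first row
occurrence so results are platform-stable. Silhouettes use
s = (B − A)/max(A, B) with s = 0 for singleton clusters and for the
degenerate A = B = 0 case; a single overall cluster is an error since B is
undefined. `between_set_sc` treats two disjoint TSS sets as the two
clusters on the same geometry; averages above 0.5 indicate a reasonable
partition and below 0.2 no cluster structure.

## Genome scan

The original analysis reports signature-bearing loci genome-wide but not
the scan mechanics, so the scan here is the package's own design: tiles of
2000 bp every 500 bp (matching the ±1000 bp feature window), features
computed at each tile midpoint, and two selectable scoring paths —

* `rule`: the tile passes iff the rule-based classifier calls it rod
  (score = number of satisfied criteria out of six);
* `centroid` (default): tile features are standardized with the training
  moments and the tile passes iff strictly closer, in correlation
  distance, to the rod class centroid than to the common centroid
  (score = the margin). This reuses the geometry the silhouettes validate.

Two guards apply to every tile: an all-zero feature vector never passes,
and neither does a tile with zero DHS signal at all three stages. Open
chromatin is a precondition of a TSS-like signature, and the gate removes
the fringe artifact where a window catches the outer reads of a
neighbouring promoter but none of its DHS, leaving a shape that
standardization can tilt toward the rod centroid with a near-zero margin.

Passing tiles merge when they overlap or abut (gap ≤ `max_gap`, default 0);
the merged site keeps the best member score. Context is decided at the
site midpoint with precedence promoter > TES > exon > intron > intergenic
(the categories are reported as mutually exclusive percentages, so a site
gets exactly one); promoter and TES regions are any annotated TSS/TES
± 1000 bp, mirroring the feature window.

## The synthetic-data generator

`simulate()` is first-class, tested code that defines the conditions every
recovery check runs under. It emulates the *structure* of the real
multi-track data, not its sequence content: a small genome of 40 kb gene
slots (24 kb transcripts, three exons, a large first intron), the original
cohort structure (72 single-TSS genes, 27 two-TSS, 8 three-TSS; every
single-TSS gene rod, every multi-TSS gene exactly one rod start), and 13
bedGraph tracks whose per-TSS signal follows class-conditional laws:

* H3K4me2 PN15/PN1 ratios are lognormal, centered 10.1 (rod) and 2.6
  (common). The reported "± 2.1"/"± 0.5" spreads are used as the per-TSS
  SD of the ratio law. Read as SEM over the reported cohort sizes they
  would imply per-TSS SDs of ~13 and ~3 — distributions in which a quarter
  of rod TSS show no developmental gain, inconsistent with the cleanly
  separated two-cluster structure the signature is defined by; a
  `ratio_spread_is_sem` switch exposes that reading anyway.
* RD1 H3K4me2 sits at the PN1 level for rod TSS (signal lost with the
  rods) and at the PN15 level for common TSS (unchanged).
* DHS and PolII developmental groups are drawn with the class proportions
  tabulated in the original marker bookkeeping (rod: 6/7/87% down/up/
  strong, common: 73% down; PolII rod: 33/31/36% none/low/high, common:
  76% none). Latent DHS ratios for the down group are drawn near the
  boundary (0.75–0.98): the observed rod-down cases are marginal, and rod
  ratios are reported as widely varying. The up/strong split within the
  common increase fraction is not reported and was chosen once (16/11%).
* CRX/NRL binding is Bernoulli with class probabilities 0.73/0.08 and
  0.56/0.03; bound totals are ≥ 300 reads (reproducing the reported
  bimodality gap), unbound is exactly 0.
* Counts are negative-binomial (dispersion 30 — CV ≈ 0.2–0.35 at typical
  depths, ordinary ChIP-like variability); DHS scores carry lognormal
  noise (σ = 0.08, processed score tracks being much less noisy than raw
  counts). Each H3K4me2/DHS/PolII track gets a sequencing-depth factor
  drawn from U(0.5, 2) applied to all its values, with
  `library_size = depth × 10⁶` written alongside, so normalization has a
  real job to do; the CRX/NRL tracks keep depth 1 so the ≥ 300 bimodality
  gap survives verbatim.
* 20 planted non-TSS sites copy the rod law at intronic (first-intron,
  ≥ 6 kb from any exon or annotated start) and intergenic (≥ 4 kb past a
  TES, ≥ 12 kb from the next start) positions, with their true contexts
  recorded.

What the generator does **not** emulate: read-level data, realistic peak
shapes, background coverage, mappability artifacts, inter-locus
correlation, or the real variance structure of the source tracks (which is
unknown — the noise laws above are stated assumptions). Passing recovery
tests therefore show that the pipeline's logic is correct under its own
stated model of the data, not that the thresholds transfer to any
particular real dataset. The ~600-site genome-wide count and the real
silhouette values (0.75 / 0.5 / −0.02) depend on the original tracks and
are deliberately not reproduction targets; desk-scale runs use the
~4.4 Mb synthetic genome (about 8 800 scan tiles), a size chosen so the
full pipeline completes in seconds.

One structural consequence worth knowing: the marker bookkeeping itself
places ~6 % of genuine rod TSS in the DHS-down group, and the rule path
gates rod calls on a DHS increase, so those TSS are definitionally missed;
with count noise the expected rule-path accuracy on default conditions sits
near 95 % and fluctuates a few points across seeds. The clustering path
uses all 13 features jointly and is insensitive to this (≈ 99 %).

## Degenerate inputs and tie-breaks

* TSS closer than 50 bp within a gene collapse to one record on read
  (single-bp RefSeq isoform starts would otherwise double-count).
* Empty aggregation windows yield 0; empty tracks get library size 1 so
  normalization stays defined.
* Zero-variance columns z-scale to zeros; zero-variance rows get
  correlation distance 0.5 to everything.
* Nearest-centroid ties (equal distance to both centroids) fall back to
  the common class — absence of evidence is never a rod call.
* Degenerate t-tests (zero pooled variance) return p = 1 when means agree,
  0 otherwise.

## Known limitations

* The rule path's fixed `k4_ratio_min` gate is a package choice; the
  original partition came from clustering, which defines no explicit
  cutoff.
* Context annotation uses the site midpoint only; a site straddling a
  boundary gets the midpoint's category.
* The scan evaluates each tile independently; no joint/HMM smoothing
  beyond merging adjacent passing tiles.
* BAM/FASTQ processing, peak calling and genome-build liftover are out of
  scope; inputs must already be scored interval tracks.
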