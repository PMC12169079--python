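# Methods

This note documents the models, conventions and design choices behind
`clonescape`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic generators do and do not
emulate.

## Repertoire analysis

A clonotype table is an AIRR-style CSV (`sample_id`, `v_call`, `j_call`,
`junction_aa`, `junction`, `duplicate_count`). Rows are aggregated by clone
key before any frequency is computed, because sequencing exports often
split one clone across rows. Three clone-key conventions are supported —
`v+aa` (default: V gene with allele stripped, plus CDR3 amino-acid
sequence), `aa`, and `nt` — because platforms disagree on what defines a
clone; sharing counts between two samples can depend on this choice, so it
is a config value rather than a constant.

*Frequency* is read-weighted: clone count over the sample's total read
count. The *hyperexpansion* rule is strictly greater than the threshold
(default 0.01): a clone at exactly 1% is not hyperexpanded. Ranks order by
descending frequency with lexicographic key tie-break, so output order is
deterministic.

*Sharing* is exact key intersection; each shared clone is classified as
hyperexpanded in both samples, in one, or in neither. The report is
symmetric under swapping the samples (unique counts swap, shared count is
invariant).

*CDR3 reference matching* uses Levenshtein distance (via edlib, verified
in the tests against a dynamic-programming oracle), default maximum
distance 1 with an optional V-gene consistency requirement. Exact matching
(`max_edit_distance=0`) is available; distance 1 is the default because
antigen-annotated databases are typically queried for "similar" CDR3s, and
single-residue variants of public clones commonly share specificity.

## Zonation

Zone construction uses the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`) with the pixel size as the
sampling so all distances are metric (μm), not chamfer approximations.
The limiting plate is the boundary between the portal mask and the
hepatocyte region (tissue minus portal). With band width *w* (default
50 μm, must be at least one pixel):

* portal interface = portal pixels with distance ≤ *w* to the hepatocyte
  region (inclusive band);
* portal core = remaining portal pixels;
* lobular interface = lobule pixels with distance ≤ *w* to the portal mask;
* the remaining lobule is intrasinusoidal where the sinusoid mask is set,
  extrasinusoidal elsewhere.

Every tissue pixel gets exactly one label; areas are pixel counts ×
pixel_size² × 10⁻⁶ mm². Tissue pixels not claimed by any specific mask
follow the lobule rules, since pixel classifiers trained on hepatocyte
markers leave stroma unlabelled. Bile-duct pixels remain inside the portal
zones; the duct mask is carried along only to count duct-infiltrating
cells. Bands are measured from mask boundaries as rasterised (no curve
smoothing); this convention is exact, reproducible, and verified against
brute-force nearest-neighbour distances in the tests. Halving the pixel
size changes zone areas of a fixed geometry by under 3%.

Coordinates: raster origin top-left, x rightward, y downward, cell
positions in μm; a cell belongs to the pixel `floor(x/px), floor(y/px)`.

## Spatial statistics

Zone assignment is centroid-based (cells arrive as points, as in
transcript-platform exports). Cells on background or outside the raster
are excluded from zone statistics but reported. Occupancy fractions are
taken over the selected cells, so they sum to 1; densities are counts over
zone areas, with a null density (and a warning) for a zero-area zone.

The marker-proportion comparison (e.g. Granzyme-B positivity in
clone-positive vs clone-negative CD8 cells) uses the two-sided Fisher
exact test at any table size — exactness is cheap and avoids chi-square
small-count caveats. The reported odds ratio is the sample cross-product;
a 0.5 continuity correction is applied, and flagged, only when a table
margin is zero (otherwise a single empty cell yields the honest 0 or
infinite sample OR).

Zone enrichment of a selection within a reference population is tested by
permutation: the null draws |selection| cells from the reference without
replacement, which is sampled exactly as a multivariate hypergeometric
over zone counts. The statistic is observed minus expected zone fraction;
the one-sided p has the add-one correction `(1 + #{perm ≥ obs}) / (B + 1)`,
making it valid at any B and uniform on its grid under the null (checked
by a Kolmogorov–Smirnov calibration test). Because the null depends only
on zone counts, the test is invariant to cell identities and order and is
deterministic for a fixed seed.

## Clone calling and expression

Transcript rollup counts assigned transcripts per (cell, feature) above a
quality cutoff (default `min_qv = 20`, a common in situ platform
convention). Unassigned transcripts are tallied separately; transcripts
referencing unknown cells are an error, not a silent drop.

A cell is clone-positive iff it is of the eligible type (default CD8 T
cell) and its summed clone-probe count reaches `min_transcripts`
(default 1). The assigned clone is the argmax probe; exact ties are called
*ambiguous* — counted as clone-positive but excluded from per-clone
frequencies, which are fractions of all eligible cells. Raising
`min_transcripts` can only shrink the positive set (tested property).

Bleed-through is quantified, not corrected: for each clone probe the share
of assigned transcripts per recipient cell type, the unassigned share, and
the outside-eligible fraction (1 − eligible share). Correction by
probabilistic reassignment is out of scope.

Expression summaries use median-total normalisation — each cell scaled by
(median total count over all cells) / (cell total) — then log1p. The
dot-plot summary reports percent expressing (count ≥ 1) and the per-gene
z-score of group mean expression across groups. Differential expression
uses the two-sided Wilcoxon rank-sum test per gene on normalised log1p
values, Benjamini–Hochberg adjustment across genes, and a fold-change
gate: significant ⇔ log2FC > 0.25 (up in the positive group) and
p_adj < 0.05. log2FC is computed on group means of normalised counts with
a 10⁻⁹ pseudo-count. Genes constant across both groups get p = 1. The
MAIT check reports the fraction of clone-positive cells with count ≥ 1 for
both KLRB1 and TRAV1-2.

Because normalisation divides by per-cell totals, a strongly shifted gene
slightly deflates its own fold change (it inflates the totals of the group
expressing it). The effect scales with the gene's share of the cell total;
with panel-scale totals (hundreds of counts) it is a ~2% bias, visible in
the recovery tests as a small downward pull on the estimated log2FC.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis assumes,
with every parameter recorded in a ground-truth manifest:

* **Repertoire pairs.** Designated shared clones receive forced expected
  frequencies (the "one dominant + few hyperexpanded" shape; the bundled
  study-like preset forces a 16% / 14.5% top clone, 12 and 9 hyperexpanded
  clones, 59 shared, 10-of-12 persistence); remaining clones draw sizes
  from a discrete power law (zipf, exponent 2 by default), optionally
  capped so no tail clone crosses the hyperexpansion threshold, and read
  counts are multinomial at 10⁶ reads in the preset (10⁵ by default). Each
  clone keeps at least one read so clone totals are exact. CDR3s are
  random valid sequences (C…F, length 8–20, 20-letter alphabet) with
  optional injected reference sequences; nucleotide CDR3s are codon
  back-translations.
* **Tissue.** Portal tracts are non-overlapping jittered disks, each with
  one bile duct; sinusoids are random-walk polylines dilated to 8 μm,
  added until a target fraction of the lobule is covered. All geometry is
  sampled in physical units, so one seed gives the same tissue at any
  raster resolution. Defaults (3 × 3 mm at 2 μm/px, five tracts of
  ~110 μm radius, 10% sinusoid fraction) approximate a human liver
  section; the study does not report its section's geometry, so these are
  free, documented knobs.
* **Cells.** Homogeneous Poisson placement per zone and stratum; the CD8
  pool is split into clone-labelled subpopulations whose density is
  multiplied by an enrichment factor in the portal interface. Marker flags
  are independent Bernoulli draws per (marker, group).
* **Transcripts.** Per-cell Poisson counts per feature; clone probes fire
  at a "self" rate only in their own clone's cells; clone-labelled cells
  may carry shifted programmes for ordinary genes (known fold changes). A
  Bernoulli fraction of transcripts is reassigned to the nearest other
  cell (bleed-through), keeping its jittered position; counts are
  conserved. Quality values are uniform on [20, 40] so the default filter
  keeps every synthetic transcript and count-recovery tests are exact.

Not emulated: optics and segmentation error beyond bleed-through,
cell-shape effects (cells are points), spatial correlation of expression,
V(D)J recombination statistics, batch effects. Passing recovery tests
therefore shows the *estimators* are correct under the stated model, not
that real tissue satisfies the model.

## Problem sizes and numerical conventions

The test and acceptance runs use deliberately moderate sizes chosen to
give comfortable statistical margins: repertoires of 189/508 clones at
10⁵–10⁶ reads; a 3 × 3 mm tissue at 2–4 μm/px; ~10⁴–10⁵ transcripts for
bleed-through recovery; 200/2000 cells for fold-change recovery;
999 permutations (199 in calibration sweeps); 100–500 replicates for null
calibration. Determinism: one global seed fans out to fixed per-stage
child seeds; identical configs give byte-identical outputs, including
permutation p-values.

Tie and edge conventions worth knowing: interface bands are inclusive
(≤ band width); rank ties break lexicographically; clone-call ties are
ambiguous rather than arbitrarily assigned; the permutation p never
returns 0 (add-one correction); an empty portal mask yields a pure-lobule
map rather than an error; a zone with zero area and requested cells warns
and reports a null density.

## Known limitations

* Bleed-through inflates clone-positive calls (the demo shows ~4.2%
  called vs 3.3% simulated); only quantification, not correction, is
  provided.
* The five-zone decomposition depends on the input masks; no smoothing or
  classifier post-processing is applied, so mask noise propagates to the
  interface bands.
* CDR3 matching at distance 1 can link clones that merely resemble a
  reference sequence; V-gene filtering reduces, but does not remove, this.
* Fisher's exact test is conservative for very large tables; with the
  study-scale group sizes this is immaterial for the reported comparison.
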