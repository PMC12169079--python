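# clonescape

Spatial tracking of hyperexpanded T cell clones in liver tissue.

`clonescape` re-implements, as a reusable and tested Python pipeline, a
spatial clone-tracking analysis for T-cell-mediated liver injury (the
motivating case is SARS-CoV-2 vaccine-associated liver injury, SVALI). It is
aimed at computational immunologists and spatial-biology analysts who have:

* bulk **TCRβ clonotype tables** from longitudinal samples (e.g. a biopsy
  and a later explant),
* **binary tissue masks** for hepatocyte parenchyma, portal tracts,
  sinusoid lumina and bile ducts,
* a segmented **cell table** (positions, cell types, marker flags), and
* an in situ **transcript table** (Xenium-style export) that includes
  clone-specific CDR3 probes.

## What it computes

**Repertoire** (`clonescape.repertoire`). Clonotypes are keyed by V gene +
CDR3 amino-acid sequence (configurable). For each sample the clone
frequency is `f_i = c_i / Σ c_j`; a clone is *hyperexpanded* when
`f_i > 0.01` (strict, i.e. "more than 1% of all TCRβ-CDR3 reads").
Sharing between two samples is exact clone-key intersection, with each
shared clone classified by where it is hyperexpanded
(both / first only / second only / neither). CDR3s are matched against an
antigen-specificity reference (e.g. spike-epitope-specific clones) by
Levenshtein distance ≤ *k* (default 1).

**Zonation** (`clonescape.zonation`). Exact Euclidean distance transforms
on the metric pixel grid split the tissue into five zones: portal core,
portal interface (portal pixels within 50 μm of the limiting plate),
lobular interface (lobule pixels within 50 μm of the portal tract), and
the remaining lobule split into intra- and extrasinusoidal compartments.

**Spatial statistics** (`clonescape.spatial`). Cells are assigned the zone
of the pixel under their centroid; per-zone occupancy fractions, densities
(cells/mm²) and marker-positive fractions follow. Marker proportions
between two cell groups are compared with the two-sided Fisher exact test;
zone enrichment of a cell subset within a reference population uses a
permutation test (draws without replacement, add-one-corrected p).

**Clone calling** (`clonescape.clone_calling`). Transcripts are rolled up
per cell; a CD8 T cell is clone-positive when it carries ≥ 1 clone-probe
transcript, with ties called ambiguous. Bleed-through is quantified as the
share of clone-probe transcripts landing outside the eligible cell type.
Differential expression between clone-positive and clone-negative CD8
cells uses the Wilcoxon rank-sum test on median-total-normalised log1p
counts with Benjamini–Hochberg adjustment (significant:
log2FC > 0.25, p_adj < 0.05).

**Synthetic data** (`clonescape.synthetic`). Every stage has a generator
with known ground truth: repertoire pairs with forced top-clone
frequencies and a power-law tail, lobule/portal raster geometry,
zone-wise Poisson cell placement with portal-interface enrichment, and
per-cell Poisson transcripts with a controlled nearest-neighbour
bleed-through rate.

## Worked example

The built-in demo simulates a full dataset shaped like the study
(biopsy/explant repertoires; three clone probes at within-CD8 frequencies
2.35% / 0.54% / 0.42%; 3× portal-interface enrichment; 30% bleed-through)
and runs every stage:

```python
import clonescape as cs

config = cs.default_config(seed=7)
results = cs.run_pipeline(config, outdir="demo_run")

sharing = results["sharing"]
print(sharing.n_shared, sharing.persistence_counts)
print(results["call_summary"])
```

prints (numbers from this exact run):

```
59 {'hyper_in_both': 3, 'hyper_in_a_only': 7, 'hyper_in_b_only': 0, 'hyper_in_neither': 49}
{'n_eligible': 5458, 'n_tcr_pos': 230, 'n_ambiguous': 0,
 'tcr_pos_fraction': 0.0421,
 'per_clone_counts': {'clone1': 162, 'clone2': 40, 'clone3': 28}, ...}
```

i.e. 59 clones are shared between the two simulated samples, 3 of them
hyperexpanded in both (top clone 16.0% in the biopsy, 14.5% in the
explant), and 230 of 5458 simulated CD8 cells are called clone-positive.
The clone-positive fraction (4.2%) exceeds the simulated 3.3% because 30%
bleed-through creates false positives — the same artefact the in situ
platforms show. The differential-expression table recovers the simulated
residency programme (KLRB1 up, log2FC ≈ 1.0 under bleed-through dilution):

```
 gene  log2_fold_change  p_adj   pct_pos  pct_neg  significant
KLRB1            1.0114  0.0000  37.3913  18.6878         True
SAMD3            0.7270  0.0000  30.4348  17.0237         True
```

and the permutation test flags the portal interface as the most enriched
zone for clone-positive cells (observed 3.5% of labelled cells vs 1.5%
expected, p = 0.027 at this demo size).

The same stages are available from the shell:

```bash
clonescape simulate --seed 7 --outdir demo_data
clonescape repertoire --sample-a demo_data/clonotypes_a.csv \
    --sample-b demo_data/clonotypes_b.csv --out sharing.json
clonescape zonate --hepatocyte demo_data/masks/hepatocyte.tif \
    --portal demo_data/masks/portal.tif --sinusoid demo_data/masks/sinusoid.tif \
    --duct demo_data/masks/duct.tif --pixel-size 2 --band 50 --out zones.tif
clonescape run --seed 7 --outdir demo_run
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical conventions and known limitations.
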