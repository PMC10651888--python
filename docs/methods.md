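# Methods

This note documents the models, parameter choices and numerical decisions
behind `sgcap`, and what the synthetic-data generators do and do not emulate.

## Differential enrichment (module `enrichment`)

Counts are modeled as negative binomial with mean m and dispersion d,
Var = m + d·m² — the parameterization shared by mainstream RNA-seq DE tools.
The three standard contrasts of a proximity-labeling experiment
(post-vs-pre enrichment; +PA vs omit-probe; bait-fused vs untargeted
photocatalyst) are each tested as a two-group comparison:

- **Size factors** are median-of-ratios: per sample, the median over
  reference genes (nonzero in every sample) of count / per-gene geometric
  mean. Samples identical up to a global scale c split as (1/√c, √c).
- **Dispersions** are per-gene moment estimates on normalized counts,
  d̂ = (s² − m̄)/m̄², with s² the pooled *within-group* variance so real
  condition effects do not inflate the estimate. A mean–dispersion trend
  a₀/m̄ + a₁ is fitted by least squares over the genes with positive d̂, and
  each informative gene's final dispersion is the geometric mean of d̂ and
  the trend (log-space shrinkage, equal weights). A gene whose raw estimate
  is non-positive (sub-Poisson sample variance) carries no information about
  a positive dispersion; it takes the trend value outright. This fallback is
  deliberate: shrinking a floored near-zero estimate instead would assign
  those genes (~6% at 2×3 replicates) dispersions around 10⁻⁵, overstate
  their precision, and push the null rejection rate of the Wald test from
  ~0.065 to ~0.084 at α = 0.05 in the 3v3, d = 0.05 regime the test suite
  checks. Final values are floored at 10⁻⁸.
- **The Wald test** uses group means on the normalized scale
  q = Σk / Σsf (the size-factor-weighted mean), log₂FC = log₂(q_A/q_B) with
  a 0.5 pseudo-offset only when a group mean is exactly zero (never inside
  the likelihood), and a standard error from the observed Fisher information
  of the NB log-link model, I(log q) = Σ_s μ_s/(1 + d·μ_s). Two-sided normal
  p-values; genes with all-zero counts in both groups are untested (missing
  p and p_adj). No independent filtering, fold-change shrinkage or outlier
  handling is applied; the implementation is a documented approximation, not
  a re-implementation of any specific DE tool, and externally produced
  contrast tables can be read in instead (`read_contrast_table`).
- **Multiple testing** is Benjamini–Hochberg within each contrast over its
  tested genes only (statsmodels' step-up; verified against the hand
  formula in the tests).

**Classification** uses strict inequalities: enriched means log₂FC > 0.3 and
p_adj < 0.05; depleted means log₂FC < −0.3, p_adj < 0.05. SG-proximal is the
intersection of the three enriched sets; SG-excluded the intersection of the
depleted sets of contrasts 1 and 3. Missing p_adj never passes. A two-table
mode exists but must be requested explicitly. The rule is monotone: raising
the fold-change cutoff or lowering α can only shrink both sets.

## Set-level analyses (module `setops`)

Exact set semantics throughout. Two-condition comparisons partition the
union into {A-specific, shared, B-specific} with percentages relative to the
union, one decimal. Basal-vs-stress categorization: basal-specific =
basal ∖ ∪stress; pre-existing = basal ∩ ∪stress; de novo = ∪stress ∖ basal,
with sub-counts present in *all* stress sets reported for the latter two.
Overlap significance is the exact hypergeometric upper tail
P(X ≥ |A∩B|), X ~ Hypergeom(N, |A|, |B|) (scipy; validated against
brute-force subset enumeration for N ≤ 12). The universe is always reported;
when contrast tables are available the natural choice is the genes tested in
both analyses, otherwise the union of the supplied lists.

## RNA features (module `features`)

Each gene is represented by its longest isoform (total spliced length; ties
break to the lexicographically smallest transcript id). AU content is
(#A + #U)/(#A + #U + #G + #C) with ambiguous bases excluded from both
numerator and denominator; DNA T is mapped to U on input. Empty regions have
length 0 and missing AU. m⁶A density is 1000·count/len_total. Non-coding
representatives keep len_cds = 0 and drop out of CDS/UTR comparisons while
retaining total length and AU. Translation efficiency is an external
per-gene table (log₂ RPF/RNA); absent or "NA" entries are missing, never
zero, and are excluded from comparisons.

Between-set comparisons use the two-sided unpaired Mann-Whitney U test:
U = #{a > b} + ½·ties; exact null distribution when min(n₁, n₂) ≤ 8 with no
ties (validated against full enumeration for n₁+n₂ ≤ 10), otherwise the
normal approximation with tie and continuity corrections. Significance
stars: ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001.

m⁶A bin proportions default to {0, 1–2, 3–5, ≥6} sites per RNA
(configurable; figure-level bins are a presentation choice), and the mean
sites per RNA is the arithmetic mean over set members present in the
feature table.

## Kinetic clustering (module `clustering`)

The trajectory matrix spans the union of the per-timepoint proximal lists;
each cell is that timepoint's targeted-vs-untargeted log₂FC. Genes untested
at a timepoint are imputed as 0 (no measured enrichment) and flagged so a
sensitivity analysis can drop them. Rows are z-scored (sample SD; constant
rows become all-zero) — the heatmap-tool convention for row scaling — so the
clustering groups trajectory *shapes*, not magnitudes. Distances are
Euclidean and linkage is complete. The tree is cut after exactly n−k merges
(`cut_tree`), which guarantees exactly k non-empty clusters even under tied
merge heights, where a maxclust-style distance cut can undershoot. Clusters
are renumbered 1..k by descending mean unscaled T0 value, so cluster 1 is
always the most stress-enriched class. k defaults to 4, matching the four
disassembly kinetic classes (fast dissociation, slow dissociation, early
re-enrichment, late re-enrichment).

## smFISH quantification (module `smfish_quant`)

Detection operates on the maximum-intensity projection of each channel (a
per-plane mode is available behind a flag). The granule mask is the set of
cell-ROI pixels strictly above a user threshold (the manual-threshold
workflow) or an Otsu fallback ("auto"). Puncta candidates are cell pixels
with intensity ≥ fold_threshold (default 2.0) times the mean intensity over
the cell ROI — the cell-restricted mean is robust to empty background
framing — grouped into 8-connected components; components below min_area_px
(default 12 px, with 15 as the documented alternative for larger probes) are
discarded, and a QC warning flags any single component covering more than a
quarter of the cell (the failure signature of a flat image under the ≥
rule). A punctum is "inside" the granule iff its rounded centroid pixel is
in the mask (unambiguous for boundary-straddling spots; an any-overlap rule
is available behind a flag). The enrichment level E is the density ratio
defined in the README; it is undefined (flagged, NaN) when the SG area is
zero, the SG covers the whole cell, or no puncta pixel falls outside the SG.
E is invariant under uniform rescaling of the FISH channel because both the
threshold and the mask scale together.

ROI polygons are 0-based pixel-center coordinates; rasterization counts
boundary pixels as inside (shapely `covers`), so a square (0,0)–(9,9) on a
10×10 grid has area exactly 100.

## Synthetic data (module `synthetic_data`)

All generators are pure functions of (spec, seed) via a single
`numpy.random.Generator` seeded once per call.

- **Counts**: log-normal baseline means (default ln-scale μ = 5, σ = 1,
  i.e. median ≈ 150 counts), gamma-Poisson NB sampling, per-sample size
  factors (log-normal, renormalized to geometric mean 1), and planted
  multiplicative effects targeted at metadata-matched samples. The canonical
  labeling design mirrors the study layout — two replicates per bait-line
  condition and four untargeted controls — and a single planted effect on
  the (targeted, +PA, post) group makes all three standard contrasts see the
  same fold change, exactly as a genuinely SG-enriched transcript would.
- **Annotation**: one contig per gene, Poisson region lengths (defaults
  200/1500/1000 nt for 5′UTR/CDS/3′UTR — mRNA-like proportions), per-region
  AU targets (0.40/0.45/0.60; 3′UTRs are the AU-rich region), Poisson m⁶A
  sites at a per-kilobase density, Gaussian log₂ TE, random strand, and
  optional shorter second isoforms to exercise longest-isoform selection.
  Realized AU concentrates around the target by binomial concentration
  (within 0.05 for regions ≥ 500 nt).
- **Images**: an elliptical cell, disk granules, disk puncta (radius 2 px →
  13 px, above the 12 px area filter) with centers separated enough that
  noise-free components never merge and eroded placement so every disk lies
  inside the cell. Amplitudes (background 50, puncta +400) keep detection
  exact without noise. Noise is Poisson shot noise plus additive Gaussian
  read noise — the standard fluorescence model. Dense placements can
  geometrically saturate the granule interior, so the returned truth records
  the *realized* inside fraction, which is the reference for recovery tests.
- **Time courses**: archetype log₂FC triples plus i.i.d. Gaussian noise;
  defaults are the four shape-distinct kinetic classes above. Distinctness
  is deliberately evaluated in z-scored space because that is where the
  clustering operates.
- **Study-geometry gene lists**: synthetic identifiers arranged into the
  disjoint overlap blocks of the published condition lists (sizes declared
  in `StudyOverlapDesign`), so every set-level statistic downstream is fully
  determined. These are synthetic stand-ins: the identifiers are not real
  gene ids, and only the overlap geometry is meaningful.

What the generators do **not** emulate: GC/length sampling biases of library
preparation, batch effects, multi-factor designs, sequence motifs, realistic
optics (PSF, 3D granule morphology), or multi-cell fields. Passing recovery
tests therefore demonstrates correctness of the computations under the
declared model, not robustness to every artifact of real data.

## Problem sizes and determinism

The test-suite and acceptance-script simulations use 40–2000 genes,
200 trajectory genes, and single 200×200-px cells — sizes at which every
statistical property checked (null calibration, planted recovery, cluster
recovery, colocalization error) is already stable, as the fixed-seed results
confirm. Every stochastic operation takes an explicit seed; identical
config + seed reproduces byte-identical outputs (hashed in the tests).

## Known limitations

- The NB Wald test is a plug-in approximation: with 2–3 replicates per group
  its null rejection rate sits slightly above nominal (~0.06–0.07 at
  α = 0.05) rather than exactly at it; the classification criterion's triple
  intersection further suppresses false positives.
- Exact DESeq2 parity is a non-goal; published per-gene statistics will
  differ from the built-in test, which is why externally computed contrast
  tables are first-class inputs.
- The hypergeometric universe for published comparisons is not recoverable
  from list files alone; reported p-values always state the universe used.
- Image quantification assumes one manually outlined ROI per cell; there is
  no segmentation, spot fitting or deconvolution.
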