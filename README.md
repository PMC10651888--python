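# sgcap

Analysis toolkit for stress-granule (SG) proximity-labeling RNA-seq and its
companion smFISH imaging validation.

Photocatalytic proximity labeling (CAP-seq) tags RNAs near a bait protein —
here G3BP1, the SG scaffold — in live cells: photo-oxidized RNA is captured
with a propargylamine (PA) probe, biotinylated, enriched on streptavidin and
sequenced. Deciding which transcripts are genuinely SG-proximal requires
combining three negative-control contrasts, and the downstream biology
(stress specificity, basal G3BP1 interactions, disassembly kinetics, RNA
sequence features, single-molecule imaging validation) is all built on that
call. `sgcap` implements the full downstream workflow from gene-level count
matrices onward, plus synthetic-data generators with known ground truth so
every stage is testable without any external download.

## The core statistics

**Three-contrast classification.** For each labeling experiment three
two-group comparisons are tested on negative-binomial counts
(Var = m + d·m², median-of-ratios normalization, moment/trend dispersions,
Wald test, Benjamini–Hochberg FDR):

1. post- vs pre-streptavidin enrichment (bait line, +PA);
2. +PA vs omit-probe control;
3. bait-fused vs untargeted photocatalyst.

A transcript is **SG-proximal** when log₂FC > 0.3 and p_adj < 0.05 in *all
three* contrasts, and **SG-excluded** when log₂FC < −0.3 and p_adj < 0.05 in
contrasts 1 and 3. Externally computed contrast tables (e.g. DESeq2 exports)
can be supplied in place of the built-in test.

**Set-level analyses.** Condition lists are compared with exact set algebra
(stress-specific / stress-independent; basal-specific / pre-existing /
de novo; cell-type sharing) and hypergeometric upper-tail overlap tests.

**RNA features.** Per gene, the longest isoform contributes 5′UTR/CDS/3′UTR
lengths, AU content per region, m⁶A site density (sites per kilobase), and
translation efficiency (log₂ RPF/RNA from an external table); sets are
compared with two-sided Mann-Whitney U tests (exact for small groups).

**Disassembly kinetics.** Per-gene log₂FC trajectories over recovery
timepoints (T0, T1, T3) are z-scored and clustered by complete-linkage
hierarchical clustering (Euclidean, k = 4 by default).

**smFISH quantification.** Maximum-intensity projection; granule mask by
threshold inside a hand-drawn cell ROI; RNA puncta as 8-connected components
≥ 2× the mean cell intensity and ≥ 12 px; colocalization fraction
(puncta centroids inside the granule mask); and the enrichment level

    E = (puncta px inside SG / SG area) / (puncta px outside SG / (cell − SG area))

## Worked example

Simulate a 500-gene three-contrast labeling experiment (50 planted enriched
transcripts at log₂FC = +2, 20 depleted at −2), test all three contrasts and
classify:

```bash
sgcap --out-dir demo --seed 17 run --n-genes 500
```

The final stage reports

```
  { "stage": "classify", "status": "ok", "n_proximal": 49, "n_excluded": 21, ... }
```

49 of the 50 planted enriched genes pass all three contrasts at the
log₂FC > 0.3, p_adj < 0.05 cutoffs (one planted gene narrowly misses in one
contrast), and the excluded call recovers the 20 planted depleted genes plus
one borderline null gene — the false-positive rate expected at these
thresholds. Per-contrast tables (`demo/contrast_*.tsv`) carry baseMean,
log₂FC, SE, p and p_adj per gene; `demo/proximal.tsv` and `demo/excluded.tsv`
are plain gene lists.

Gene-set comparisons work directly on list files:

```bash
sgcap --out-dir demo compare --sets arsenite.txt --sets sorbitol.txt
```

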