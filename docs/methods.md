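# Methods

`laminamap` answers a spatial question about dissociated transcriptomic data:
given neuron subtypes defined purely by clustering of single-nucleus RNA-seq
counts, in which anatomical lamina of a layered structure (here the mouse
superior colliculus, SC) does each subtype live?  Because the nuclei are
dissociated, the matrix itself carries no position.  The package recovers
position indirectly: it finds each subtype's most *specific* marker genes and
reads their spatial expression off in-situ-hybridization (ISH) images whose
laminar anatomy is known.

## Pipeline

### 1. Quality control

Cells are kept when every rule holds (all bounds inclusive on the keep side,
because the discard rules are phrased strictly — "below 800", "above 20,000",
"greater than 3%"):

| parameter | droplet snRNA-seq default | patch-seq preset |
| --- | --- | --- |
| detected genes (nGene) | 800 – 6000 | 200 – 10 000 |
| total UMIs (nUMI) | ≤ 20 000 | – |
| mitochondrial fraction | ≤ 0.03 | ≤ 0.10 |
| spike-in (ERCC) fraction | – | ≤ 0.05 |
| doublet score (externally computed) | ≤ 0.16 | – |
| gene kept if expressed in ≥ | 3 cells | 2 cells |

Doublet scores are consumed from a `(cell_id, score)` table, never computed
here.  The QC report records, per dropped cell, the first rule it failed
(rules are evaluated doublet → nGene → nUMI → mito → ERCC).

### 2. Normalization

`value = ln(1 + 10^4 · count / nUMI)` per cell.  Zeros stay zero and the
layer stays sparse.

### 3. Differential expression (one subtype vs the rest)

* **Wilcoxon route** (droplet data): two-sided rank-sum test per gene.  With
  ≤ 10 cells in total the p-value is computed by full enumeration of the
  C(n, n₁) rank assignments of the midrank sum; above that, the normal
  approximation with tie and continuity correction.  P-values are
  Benjamini–Hochberg adjusted within each subtype; a gene is flagged when
  `p_adj < 0.05`.
* **ROC route** (patch-seq): classification power `|2·AUC − 1|`, with AUC the
  Mann–Whitney probability (ties count ½) that an in-group cell exceeds an
  out-group cell; flagged when `power > 0.4`.  The signed AUC is also
  reported, so either convention can be inspected.

Both routes additionally require positive enrichment, `log_fc ≥ 0.25`, where
`log_fc` is the difference of per-group means of the natural-log normalized
values.  Layer markers are by construction *enriched* genes; without the
direction constraint a strongly depleted gene would qualify.

### 4. Specificity score and reference genes

For each flagged gene, the per-subtype mean expression profile is computed on
the *linear* normalized scale (expm1 of the log values, then averaged — the
usual convention for Jensen–Shannon specificity; averaging logs compresses
fold changes and blurs markers against borderline DEGs).  The profile is
normalized to a distribution `p_g` over the K subtypes and scored against the
one-hot indicator `e_k` of each subtype:

    S_gk = 1 − sqrt( JSD(p_g, e_k) ),   JSD in bits (base-2 entropies)

`S_gk = 1` iff the gene is expressed in subtype k only.  Per subtype, flagged
genes are ranked by `S_gk` for their own subtype (ties: smaller adjusted p,
then gene id) and the top 10 become that subtype's reference genes — ten
genes, because the spatial call uses their mean behaviour and a handful of
noisy slices would otherwise dominate.

### 5. ISH quantification

Each reference gene contributes one or more grayscale slices with a mask for
each of the four SC laminae (SuG, Op, InG/InWh, DpG) and one
*weakest-signal* background region.  ROI choice is an input — the published
procedure draws them by hand; `propose_background` (sliding-window minimum
mean) is offered as a clearly-labeled convenience extension.  Per slice:

1. min–max rescale to 8-bit (constant slice → all zeros);
2. IsoData (iterative-intermeans) threshold on the 256-bin histogram — the
   default of the standard ImageJ threshold dialog — classifying
   `pixel ≥ level` as signal; a manual level can override it;
3. area fraction = percent of signal pixels inside each ROI;
4. layer intensity = `max(0, AF(layer) − AF(background))`; negative
   differences are noise, hence the clip at zero.

Slices of one gene are combined by the arithmetic mean (the sensible default
when slices are exchangeable; nothing in the data weighs one slice above
another).

### 6. Layer scores, inference, assignment

Per subtype, the genes × 4 intensity table is min–max normalized per gene
(constant rows → zeros), and

    layer score = ln( mean over genes of normalized intensity + ε ),  ε = 1e-3

ε only keeps the log finite; score *ordering* equals the ordering of the
means, and inference never uses the scores: a one-way ANOVA across the four
layers (genes as replicates) plus a Tukey HSD post hoc over the six layer
pairs is run on the normalized intensities — the last processing step before
the test.  The top-scoring layer is assigned iff the ANOVA p < 0.05 **and**
its Tukey p against every other layer is < 0.05; otherwise the subtype is
left *unassigned*, the honest call for neurons spanning several laminae.
Tukey HSD was chosen for the (unspecified) post hoc because the comparison
family is exactly all layer pairs at a matched family-wise α; the
winner-beats-all rule is deliberately stricter than the ANOVA alone.

A degenerate ANOVA input (all values identical) returns F = 0, p = 1 and all
post hoc p = 1 rather than NaN, so a perfectly flat subtype is unassigned,
not an error.

### 7. Cluster correlation mapping

To place patch-seq (Smart-seq) clusters onto the droplet atlas, the package
computes the Pearson correlation between cluster mean profiles over a shared
gene set (≥ 3 genes) and reports the argmax per row as the best match.
Profiles may be plain log-normalized means or an externally batch-integrated
matrix — anchor-based integration itself is out of scope, which is the one
deliberate divergence from the published Seurat-CCA preprocessing.
Correlations with a constant profile are undefined and reported as missing,
never as zero.

## Synthetic data

The generator produces the two inputs with known truth:

* **Counts**: gamma-Poisson (negative binomial, `var = μ + αμ²`, default
  α = 0.5) background with per-gene lognormal baseline means around
  `nb_mean = 1` UMI/cell; 2000 genes × 4 subtypes × 50 cells by default, so
  that per-cell nGene (~1100) and nUMI (~2000) fall inside the real QC
  window.  Each subtype gets 10 planted markers whose mean is multiplied by
  `marker_fold = 8` — the strong, specific enrichment expected of curated
  layer markers.  2% of genes are tagged mitochondrial and 2% spike-in;
  doublet scores are drawn from Beta(2, 30), putting a realistic few percent
  of cells above the 0.16 cutoff.
* **Images**: the four laminae are horizontal bands (each 20% of a 240×200
  image) with a background strip below; geometry is irrelevant because
  quantification is mask-driven.  Signal pixels are Bernoulli(0.4) inside a
  gene's true layer and Bernoulli(0.02) elsewhere, drawn at gray 220 on a
  base of 30 with Gaussian noise (σ = 8) and clipped to [0, 255].

Determinism: every draw flows through one `numpy.random.Generator` seeded
from `(config.seed, stage-salt)`, so a seed + config pair reproduces the
bundle bit-for-bit.  By default only planted markers receive stored slices;
`StudyBundle.image_provider` additionally synthesizes deterministic
no-preference slices for any other gene (a background gene has no planted
lamina, so a uniform sparse stain *is* its ground truth), while plain
dict-of-images input enforces the strict missing-image error.

What the generator does **not** emulate: curved laminar anatomy,
slice-to-slice registration error, chromogenic color, cell-type-correlated
library size, ambient RNA, batch effects.  Passing tests therefore show the
statistics and the image quantification are implemented correctly and that
the pipeline recovers clean planted structure; they do not show robustness
to real histology or real batch structure.

## Experiment sizes

The recovery and null experiments run 50 replicate studies each (the size at
which a 95% recovery criterion is resolvable), with the defaults above; the
automatic-threshold check uses 50 images.  These sizes are the package's
reporting convention, reused by both the test suite and
`scripts/acceptance.py`.

## Known limitations

* ISH quantification assumes grayscale expression stains; no color
  deconvolution.
* The ANOVA treats genes as independent replicates; correlated reference
  genes (e.g. co-regulated paralogs) overstate the effective n.
* The Wilcoxon exact path enumerates rank splits only up to n = 10 cells
  total; beyond that the normal approximation is used even when counts are
  heavily tied.
* Cluster mapping does not integrate batches; feed it integrated profiles
  when platforms differ.
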