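# cnvae

Copy-number inference from single-cell RNA-seq with a two-stage
variational autoencoder.

Tumour samples profiled by scRNA-seq mix aneuploid tumour cells with
diploid immune and stromal cells. Because transcript abundance tracks
genomic dosage, copy-number variants (CNVs) leave a multiplicative
footprint on expression. `cnvae` exploits that footprint to (i) find the
diploid cells in a mixed population **without marker genes, cell-type
signatures, or any prior labels**, and (ii) infer integer copy-number
profiles for every cell and every tumour clone. It is aimed at cancer
genomics researchers who have a UMI/read count matrix (10x-style MTX or
dense TSV) and a gene annotation, and want clone karyotypes and
single-cell copy profiles without matched DNA sequencing.

## Method

Counts are genome-sorted, QC-filtered, library-normalized, and averaged
into bins of 25 consecutive genes (cells × bins matrix **X**). Then:

1. **Stage 1** — a small VAE (1 hidden layer of 128 units, 10-d latent
   *z*, negative-binomial likelihood with library-size-scaled softmax
   means and per-bin dispersion θ_b) is trained on **X**; k-means over
   the latent means over-clusters the population (k = 5). For each
   cluster the mean lag-1 Pearson autocorrelation of member profiles
   along the genome (within chromosomes) is computed; multi-bin CNVs
   make neighbouring bins co-vary, so the cluster at the noise floor —
   the *least* genomically autocorrelated — is the diploid population.
   The baseline b_j is the per-bin mean over diploid cells, and the
   pseudo copy matrix is C_ij = 2 · X_ij / b_j (diploid ≙ 2).
2. **Stage 2** — the VAE is retrained on C with a Gaussian likelihood;
   its reconstruction is the denoised copy estimate. Per clone
   (non-diploid cluster), breakpoints are called on the clone-mean track
   by binary segmentation: a split is accepted when
   2·(ℓ_split − ℓ_joint) > 3·log n, with a robust (MAD-of-differences)
   noise scale, never crossing chromosomes. Each cell's copy number per
   segment is the median of its refined bins, rounded half-away-from-zero
   into {0,…,6}; the clone profile is the per-segment mean over members.

A seeded synthetic-data generator (parametric negative-binomial diploid
expression with CNV events spiked into 80% of cells, loss copies {0,1},
gain copies {3,4,5,6}, event locations shared across aneuploid cells,
per-cell copies independent) provides ground-truthed benchmarks, and an
evaluation module scores calls by Pearson correlation, cosine
similarity, and average positional Manhattan/Euclidean distance, with
log2-ratio, CNV-category and LoH conversions for comparison against
DNA-derived references.

See `docs/methods.md` for assumptions, parameter defaults, and
limitations.

## Worked example

```python
import numpy as np
from cnvae import (
    CopyNumberPipeline, SimConfig, preprocess_counts, score,
    simulate_dataset,
)
from cnvae.simulate import bin_truth, make_annotation

# 1. a ground-truthed synthetic dataset: 500 cells x 5000 genes,
#    80% aneuploid, 6 shared CNV events
cfg = SimConfig(seed=0)
adata, truth_genes, events = simulate_dataset(cfg)

# 2. preprocess: sort by genome position, QC, normalize, 25-gene bins
binned = preprocess_counts(adata, make_annotation(cfg))

# 3. run the two-stage workflow
pipe = CopyNumberPipeline(random_state=0).fit(binned)
print(f"diploid cluster: {pipe.diploid_cluster_} "
      f"({int(pipe.diploid_mask_.sum())} cells)")

# 4. score the inferred tumour profile against the generator's truth
kept = [adata.obs_names.get_loc(c) for c in binned.obs_names]
is_aneu = adata.obs["is_aneuploid"].to_numpy()[kept]
truth_bins = bin_truth(truth_genes[kept], adata.var_names.to_numpy(),
                       [g.split(",") for g in binned.var["gene_ids"]])
report = score(pipe.cell_profiles_[~pipe.diploid_mask_].mean(axis=0),
               truth_bins[is_aneu].mean(axis=0))
print(f"clone profile: pearson={report.pearson:.3f} "
      f"cosine={report.cosine_similarity:.3f} "
      f"avg|d|={report.avg_manhattan:.3f} over {report.n_positions} bins")
```

Output:

```
diploid cluster: 4 (101 cells)
clone profile: pearson=0.990 cosine=0.997 avg|d|=0.101 over 200 bins
```

The selected cluster contains 101 cells — the 100 simulated diploid
cells plus one aneuploid straggler. The inferred tumour-clone profile
(mean integer copy over all cells called aneuploid) correlates with the
ground-truth clone profile at r = 0.99 with cosine similarity 0.997, and
deviates by about 0.1 copies per bin on average.

The same workflow is available from the shell:

```bash
cnvae simulate --n-cells 500 --n-genes 5000 --seed 0 --out-dir data/
cnvae run --input data/ --annotation data/annotation.tsv \
          --outdir out/ --seed 0
# score positional calls (chrom, pos, copy TSVs) against a reference
cnvae evaluate --estimate est_positions.tsv --truth ref_positions.tsv \
               --out report.json
```

`run` writes cluster labels, the diploid baseline, pseudo/refined copy
matrices, breakpoints, per-cell integer profiles, BED-like clone
profiles, and a `manifest.json` with config, per-stage timings and file
checksums.

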