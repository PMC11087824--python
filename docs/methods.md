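# Methods

## Problem

Tumour samples profiled by droplet scRNA-seq mix aneuploid tumour cells
with diploid stromal and immune cells. Because transcript abundance
correlates with genomic dosage, copy-number variants (CNVs) leave a
multiplicative footprint on expression — but the footprint is buried
under gene-specific expression levels, library-size differences and
dropout. `cnvae` identifies the diploid cells in such a population
*without marker genes or prior labels*, and infers integer copy-number
profiles per cell and per tumour clone, in two stages built around one
small variational autoencoder.

## Preprocessing

Genes are annotated with genomic coordinates and sorted by
(chromosome, start); chromosomes follow the natural order 1–22, X, Y and
unplaced contigs are dropped. Cells failing any of three QC rules are
removed: total counts < 5000, detected genes < 2000, or mitochondrial
fraction > 20% (all configurable; these defaults suit real droplet data —
shallow simulated fixtures in the test suite use proportionally smaller
cutoffs). Mitochondrially encoded, HLA and cell-cycle genes are excluded
(packaged symbol lists, user-overridable; mitochondrial genes are also
matched by the `MT-` prefix) because their expression reflects genome
location or cell state rather than nuclear dosage. Each cell is scaled to
the median per-cell total, then runs of 25 genomically consecutive genes
on one chromosome are averaged into bins. Binning restarts at chromosome
boundaries; a chromosome's trailing remainder (< 25 genes) is merged into
its last bin rather than discarded, so bins at chromosome ends hold 25–49
genes and no bin ever spans two chromosomes.

## The VAE

Encoder and decoder are single-hidden-layer MLPs (128 ReLU units) with a
10-dimensional diagonal-Gaussian latent; the ELBO is reconstruction
log-likelihood minus `kl_weight` × KL(q‖N(0, I)) with `kl_weight` = 1
(no annealing). The model is implemented directly on numpy with
hand-written reverse-mode gradients and Adam (lr 1e-3, batch 128, up to
200 epochs, early stop when the full-data ELBO improves < 0.1% over 20
epochs); the gradients are validated against central finite differences
in the test suite, and all randomness (init, batching, reparameterisation
noise) flows from one seed, giving bit-stable training.

*Stage 1* trains on the binned expression matrix with a
negative-binomial likelihood: the decoder emits per-bin proportions
through a softmax, scaled by each cell's observed total (library size),
with a free per-bin dispersion — the mean/dispersion NB used throughout
the single-cell literature, evaluated through gamma functions so it
accepts the real-valued bin means. The encoder sees per-bin standardized
log1p expression; standardization matters, because copy-number signal is
*relative* variation and an unstandardized input leaves the latent space
organised by absolute expression instead.

*Stage 2* retrains the same architecture on the pseudo copy matrix with
a Gaussian likelihood (free per-bin variance, softplus mean so refined
copies stay non-negative). Its reconstruction at the posterior mean is
the denoised per-bin copy estimate passed to segmentation.

## Diploid identification and the pseudo copy matrix

Stage-1 latent means are clustered with k-means (k = 5 by default,
10 restarts, seeded). k must exceed the number of natural tumour
sub-populations enough that the diploid cells get their own cluster;
with a large, internally diverse tumour fraction a 2-way split cuts
through the tumour cells first, which is why the default over-clusters
and then *selects*.

Selection uses a per-cluster autocorrelation score. The default
(`"genomic"`) score is the lag-1 Pearson autocorrelation of each member
cell's bin profile along the genome, computed within chromosomes,
averaged over chromosomes and then over member cells (constant stretches
contribute 0). Multi-bin CNV events make neighbouring bins co-vary, so
aneuploid clusters score high while diploid profiles sit at the noise
floor: **the diploid cluster is the one with the smallest genomic
autocorrelation**. On the packaged generator the margin is wide
(≈ 0.03 for diploid clusters vs ≈ 0.31 for aneuploid ones). An
alternative `"coherence"` score (mean correlation of each member with
its cluster's mean profile, a direct homogeneity measure under the
"normal cells are less diverse" assumption) is available behind a flag;
it is less discriminative here because shared event locations also make
tumour clusters internally coherent. Ties break toward the larger
cluster, then the lower id.

The baseline expression profile is the per-bin mean over the selected
diploid cells; zero bins are floored to 0.1× the smallest positive value
so the profile can serve as a divisor (floored bins are logged). The
pseudo copy matrix is `2 × expression / baseline`, so diploid cells sit
at copy 2 by construction. If no diploid cells can be identified the run
aborts with guidance — like all baseline-normalization methods, the
approach requires normal cells in the sample.

## Segmentation and profile calling

Each non-diploid cluster becomes a tumour clone. Breakpoints are called
on the *clone-mean* refined copy track (clones share breakpoints, cells
keep their own levels), per chromosome, by greedy binary segmentation
under a Gaussian likelihood: a split is accepted when twice the
log-likelihood gain exceeds `penalty × log(n_bins)` with penalty 3.0 —
a BIC-style cost per breakpoint — and accepted segments are split
recursively. The noise scale is estimated per chromosome from the median
absolute deviation of first differences (÷√2), which the change points
being sought barely perturb. The test suite checks the greedy result
against an exhaustive dynamic-programming segmentation of the same
objective.

Per cell, each segment's copy number is the median of the cell's refined
bin values inside it, rounded half-away-from-zero and clipped to
[0, max_cn] with max_cn = 6 (matching the generator's support); the
clone profile is the per-segment mean over member cells. Diploid cells
are reported as copy 2 everywhere.

## Synthetic data generator

The generator defines the package's study conditions and is first-class,
tested code. Diploid counts are drawn from a parametric model chosen to
emulate the statistical regime of droplet scRNA-seq without conditioning
on any external dataset: gene means log-uniform on [0.05, 20] (many
weakly expressed genes, a few high expressors), negative binomial with
shared dispersion 2.0 (strong overdispersion), and log-normal per-cell
library factors with CV 0.2. Defaults: 500 cells × 5000 genes over 10
equal chromosomes.

CNVs are then spiked into exactly 80% of cells. Six events per dataset
(lengths 8–30 bins, i.e. 200–750 genes) are placed without overlap;
each event's location and type (loss or gain, equiprobable) is shared by
every aneuploid cell, while the integer copy each cell carries inside an
event is drawn independently per cell — loss ∈ {0, 1}, gain ∈ {3, 4, 5, 6}
— so aneuploid cells share a karyotype skeleton but remain diverse.
Counts are modified multiplicatively in the mean (factor c/2): binomial
thinning for losses (preserves the original draw's noise) and a fresh NB
draw at the scaled mean for gains. Ground truth is recorded per gene and
aggregated to any bin layout by per-bin mode.

What the generator does **not** emulate: gene–gene co-expression
structure, cell-type heterogeneity among the diploid cells, cell-cycle
or ambient-RNA effects, dropout beyond what the NB induces, and
sub-clonal tree structure (every aneuploid cell shares one event
skeleton). Passing the benchmark therefore demonstrates correct recovery
under realistic count noise and library variation, not robustness to
every artefact of real tumour data.

## Evaluation

Accuracy is scored by Pearson correlation, cosine similarity, and
average positional Manhattan/Euclidean distances (total distance divided
by the number of positions, making samples of different size
comparable). For cross-method or bulk-reference comparison, per-gene
calls are mapped onto the reference's genomic positions: a position
inside a called gene takes that gene's value, otherwise the value of the
nearest called gene on the same chromosome (distance to gene midpoints;
ties to the lower coordinate; never across chromosomes). Converters
produce log2(c/2) ratios (c = 0 clipped to 0.1), threshold-2
amplification/neutral/deletion categories, and LoH regions (positions
with SNP variant allele frequency < 0.1 or > 0.9 whose category is
neutral or deletion, merged into contiguous runs).

## Benchmark and problem sizes

`cnvae.benchmark` ties everything together: ten seeded replicates at the
generator's default scale (500 × 5000, 80% aneuploid, 6 events) are each
simulated, preprocessed, fitted and scored against their own ground
truth at bin level; `scripts/acceptance.py` reports the median clone
Pearson, median clone cosine, and pooled median per-cell Pearson. The
full ten-replicate benchmark takes about 1.5 minutes on one CPU. Unit
tests use smaller fixtures (120–300 cells, 1000–3000 genes) chosen so
each property under test has adequate signal while the suite stays fast.

## Numerical choices and degenerate inputs

Means inside logs are floored at 1e-10; encoder log-variances are clipped
to ±15; the per-bin input scale adds 1e-8 (constant bins map to zero
input). Constant tracks score autocorrelation 0 by convention; the
segmentation sigma is floored at 1e-4; chromosomes with < 2 bins are
never split. A NaN training loss aborts with a learning-rate hint rather
than propagating. Zero-total cells are a hard error after QC; an all-
diploid sample yields an empty clone set with a warning rather than a
crash.

## Known limitations

Total-count normalization maps each cell to the same budget, so heavily
amplified or deleted genomes are rescaled by their own mean ploidy; the
inferred *integer* levels can be compressed toward 2 even when the
profile *shape* (what the correlation metrics measure) is right. The
method inherits the field-wide requirement of normal cells in the
sample. Breakpoints are shared within a clone; private single-cell
events smaller than a bin or discordant with the clone mean are
smoothed away. Copy-neutral LoH is only annotated when SNP VAFs are
provided; the expression signal alone cannot see it.
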