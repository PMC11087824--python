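"""Ground-truthed synthetic scRNA-seq datasets with spiked CNVs.

The generator first draws a diploid expression matrix from a parametric
negative-binomial model — gene-level means log-uniform over a realistic
dynamic range, a shared dispersion, and log-normal per-cell library-size
factors — and then spikes copy-number events into a fixed fraction of
cells (80% by default).  Event locations and types (loss or gain) are
drawn once and shared by every aneuploid cell; the integer copy number
each aneuploid cell carries inside an event is drawn independently per
cell from the event type's category (loss: {0, 1}; gain: {3, 4, 5, 6}),
so aneuploid cells are diverse while sharing a karyotype skeleton.

Counts inside an event are modified multiplicatively in the mean
(factor ``c / 2``): binomial thinning for losses, which preserves the
sampling noise of the diploid draw, and a fresh negative-binomial draw at
the scaled mean for gains.

The diploid model is parametric by design: it emulates the statistical
regime of droplet scRNA-seq (overdispersed counts, library-size
variation, many weakly expressed genes) without conditioning on any real
dataset, so simulations are fully self-contained and seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad

logger = logging.getLogger(__name__)

LOSS_SET = (0, 1)
GAIN_SET = (3, 4, 5, 6)


@dataclass
class SimConfig:
    """Parameters of the synthetic-CNV generator (defaults = study conditions)."""

    n_cells: int = 500
    n_genes: int = 5000
    n_chromosomes: int = 10
    aneuploid_fraction: float = 0.8
    n_events: int = 6
    event_length_bins: tuple[int, int] = (8, 30)
    bin_size: int = 25
    nb_mean_logspace: tuple[float, float] = (0.05, 20.0)
    nb_dispersion: float = 2.0
    library_size_cv: float = 0.2
    max_cn: int = 6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.aneuploid_fraction <= 1.0:
            raise ValueError("aneuploid_fraction must be in [0, 1]")
        if self.n_genes % self.n_chromosomes != 0:
            raise ValueError("n_genes must be divisible by n_chromosomes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class CnvEvent:
    chrom: str
    start_gene: int  # index within chromosome, inclusive
    end_gene: int    # exclusive
    kind: str        # "loss" | "gain"


@dataclass
class CnvEventSet:
    """Shared event locations/types plus per-cell integer copies."""

    events: list[CnvEvent]
    per_cell_copies: np.ndarray  # aneuploid cells x events
    aneuploid_cells: np.ndarray  # indices into the cell axis


def make_annotation(config: SimConfig) -> pd.DataFrame:
    """Synthetic gene annotation: equal-sized chromosomes, 1-based coords."""
    per_chrom = config.n_genes // config.n_chromosomes
    rows = []
    for c in range(config.n_chromosomes):
        for g in range(per_chrom):
            idx = c * per_chrom + g
            start = 1 + g * 2000
            rows.append({
                "gene_id": f"G{idx:05d}",
                "chrom": str(c + 1),
                "start": start,
                "end": start + 999,
            })
    return pd.DataFrame(rows)


def simulate_diploid(config: SimConfig, rng: np.random.Generator | None = None) -> ad.AnnData:
    """Draw the diploid count matrix; gene means and library factors kept in the result."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.nb_mean_logspace
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    cv = config.library_size_cv
    if cv > 0:
        s2 = np.log1p(cv ** 2)
        lib = np.exp(rng.normal(-s2 / 2.0, np.sqrt(s2), size=config.n_cells))
    else:
        lib = np.ones(config.n_cells)

    mu = lib[:, None] * means[None, :]
    theta = config.nb_dispersion
    # NB as gamma-Poisson mixture
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    annotation = make_annotation(config)
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=[f"cell{i:04d}" for i in range(config.n_cells)]),
        var=annotation.set_index("gene_id"),
    )
    adata.var["nb_mean"] = means
    adata.obs["lib_factor"] = lib
    adata.uns["sim_config"] = {"nb_dispersion": theta}
    return adata


def _place_events(config: SimConfig, rng: np.random.Generator) -> list[CnvEvent]:
    """Choose non-overlapping event gene intervals and types."""
    per_chrom = config.n_genes // config.n_chromosomes
    occupied = {str(c + 1): [] for c in range(config.n_chromosomes)}
    events: list[CnvEvent] = []
    attempts = 0
    while len(events) < config.n_events:
        attempts += 1
        if attempts > 1000 * config.n_events:
            raise ValueError(
                f"could not place {config.n_events} non-overlapping events "
                f"(placed {len(events)}; chromosomes of {per_chrom} genes, "
                f"event lengths {config.event_length_bins} bins x "
                f"{config.bin_size} genes)"
            )
        chrom = str(rng.integers(config.n_chromosomes) + 1)
        n_bins = int(rng.integers(config.event_length_bins[0],
                                  config.event_length_bins[1] + 1))
        length = n_bins * config.bin_size
        if length > per_chrom:
            continue
        start = int(rng.integers(0, per_chrom - length + 1))
        end = start + length
        if any(start < e and lo < end for lo, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        kind = "loss" if rng.random() < 0.5 else "gain"
        events.append(CnvEvent(chrom=chrom, start_gene=start, end_gene=end, kind=kind))
    return events


def spike_cnvs(
    diploid: ad.AnnData,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ad.AnnData, np.ndarray, CnvEventSet]:
    """Introduce shared CNV events with per-cell copies into the diploid matrix.

    Returns ``(adata, truth, event_set)`` where ``truth`` is the
    cells x genes integer copy matrix (diploid rows constant 2) and
    ``adata.obs["is_aneuploid"]`` marks the spiked cells.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n_cells, n_genes = diploid.shape
    per_chrom = n_genes // config.n_chromosomes

    n_aneu = int(round(config.aneuploid_fraction * n_cells))
    aneuploid = rng.choice(n_cells, size=n_aneu, replace=False)
    aneuploid.sort()

    events = _place_events(config, rng)
    copies = np.empty((n_aneu, len(events)), dtype=np.int64)
    for j, ev in enumerate(events):
        pool = LOSS_SET if ev.kind == "loss" else GAIN_SET
        copies[:, j] = rng.choice(pool, size=n_aneu)

    counts = np.asarray(diploid.X, dtype=np.int64).copy()
    truth = np.full((n_cells, n_genes), 2, dtype=np.int64)
    means = diploid.var["nb_mean"].to_numpy()
    lib = diploid.obs["lib_factor"].to_numpy()
    theta = diploid.uns["sim_config"]["nb_dispersion"]

    for j, ev in enumerate(events):
        chrom_offset = (int(ev.chrom) - 1) * per_chrom
        cols = slice(chrom_offset + ev.start_gene, chrom_offset + ev.end_gene)
        for i, cell in enumerate(aneuploid):
            c = copies[i, j]
            truth[cell, cols] = c
            if c == 2:
                continue
            if c < 2:
                # thinning preserves the original draw's noise structure
                counts[cell, cols] = rng.binomial(counts[cell, cols], c / 2.0)
            else:
                mu = lib[cell] * means[cols.start: cols.stop] * (c / 2.0)
                lam = rng.gamma(theta, mu / theta)
                counts[cell, cols] = rng.poisson(lam)

    out = diploid.copy()
    out.X = counts
    out.obs["is_aneuploid"] = np.isin(np.arange(n_cells), aneuploid)
    event_set = CnvEventSet(
        events=events, per_cell_copies=copies, aneuploid_cells=aneuploid
    )
    logger.info(
        "[simulate] %d/%d aneuploid cells, %d events (%s)",
        n_aneu, n_cells, len(events), ",".join(e.kind for e in events),
    )
    return out, truth, event_set


def simulate_dataset(
    config: SimConfig,
) -> tuple[ad.AnnData, np.ndarray, CnvEventSet]:
    """Diploid simulation followed by CNV spiking, from one seed."""
    rng = np.random.default_rng(config.seed)
    diploid = simulate_diploid(config, rng)
    return spike_cnvs(diploid, config, rng)


def bin_truth(
    truth_genes: np.ndarray, gene_ids: np.ndarray, bin_gene_ids: list[list[str]]
) -> np.ndarray:
    """Aggregate a cells x genes truth matrix to bins by per-bin mode.

    ``bin_gene_ids`` lists, per bin, the member gene identifiers as
    produced by the preprocessing binner; genes the pipeline dropped are
    simply absent.  Using the mode keeps bin truth integer even when an
    event boundary falls inside a bin.
    """
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_cells = truth_genes.shape[0]
    out = np.empty((n_cells, len(bin_gene_ids)), dtype=np.int64)
    for b, members in enumerate(bin_gene_ids):
        cols = [gene_pos[g] for g in members if g in gene_pos]
        sub = truth_genes[:, cols]
        # mode along axis 1 over the small support {0..6}
        counts = np.stack([(sub == v).sum(axis=1) for v in range(7)], axis=1)
        out[:, b] = counts.argmax(axis=1)
    return out


def write_ground_truth(
    truth_genes: np.ndarray,
    adata: ad.AnnData,
    event_set: CnvEventSet,
    out_dir,
    truth_bins: np.ndarray | None = None,
    bin_names: list[str] | None = None,
) -> dict[str, Path]:
    """Write gene-level (and optionally bin-level) truth, labels and events as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    gene_df = pd.DataFrame(
        truth_genes, index=adata.obs_names, columns=adata.var_names
    )
    paths["truth_genes"] = out_dir / "truth_genes.tsv"
    gene_df.to_csv(paths["truth_genes"], sep="\t")

    labels = pd.DataFrame({
        "cell_id": adata.obs_names,
        "is_aneuploid": adata.obs["is_aneuploid"].astype(int).to_numpy(),
    })
    paths["labels"] = out_dir / "truth_labels.tsv"
    labels.to_csv(paths["labels"], sep="\t", index=False)

    per_chrom_bp = 2000
    rows = []
    for ev in event_set.events:
        rows.append({
            "chrom": ev.chrom,
            "start_bp": 1 + ev.start_gene * per_chrom_bp,
            "end_bp": ev.end_gene * per_chrom_bp,
            "type": ev.kind,
        })
    paths["events"] = out_dir / "truth_events.tsv"
    pd.DataFrame(rows).to_csv(paths["events"], sep="\t", index=False)

    if truth_bins is not None:
        bdf = pd.DataFrame(truth_bins, index=adata.obs_names, columns=bin_names)
        paths["truth_bins"] = out_dir / "truth_bins.tsv"
        bdf.to_csv(paths["truth_bins"], sep="\t")
    return paths
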