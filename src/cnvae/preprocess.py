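"""Preprocessing: genomic ordering, QC, normalization and gene binning.

The pipeline input is a cells x genes UMI/read count matrix held in an
:class:`anndata.AnnData`.  Preprocessing turns it into a cells x bins matrix
of mean expression, where each bin is a run of ``bin_size`` genomically
consecutive genes on one chromosome.  Binning suppresses dropout noise and
is what makes expression usable as a copy-number proxy.

All steps are deterministic; identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad

from . import gene_lists

logger = logging.getLogger(__name__)

#: recognised chromosomes, in genomic order
CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def _dense(X) -> np.ndarray:
    """Return a dense float64 ndarray view/copy of an AnnData ``X``."""
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=np.float64)


def chromosome_rank(chrom: str) -> int | None:
    """Rank of a chromosome label in genomic order, or None if unplaced.

    Accepts plain (``"7"``, ``"X"``) and prefixed (``"chr7"``) labels.
    """
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if c.upper() in ("X", "Y") else c
    return _CHROM_RANK.get(c)


@dataclass
class QcThresholds:
    """Cell-level quality-control thresholds.

    Cells are removed when total counts fall below ``min_total_counts``,
    when fewer than ``min_expressed_genes`` genes are detected, or when
    the mitochondrial fraction exceeds ``max_mito_fraction``.
    """

    min_total_counts: int = 5000
    min_expressed_genes: int = 2000
    max_mito_fraction: float = 0.20

    def __post_init__(self):
        if self.min_total_counts < 0 or self.min_expressed_genes < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


def annotate_and_sort(adata: ad.AnnData, annotation: pd.DataFrame) -> ad.AnnData:
    """Attach genomic coordinates to genes and sort columns by position.

    Parameters
    ----------
    adata
        Cells x genes counts; ``var_names`` are gene identifiers.
    annotation
        Table with columns ``gene_id``, ``chrom``, ``start``, ``end``
        (1-based inclusive coordinates).

    Genes missing from the annotation, and genes on unplaced contigs, are
    dropped (counts logged).  Column order of the result is
    (chromosome rank, start, gene_id).
    """
    ann = annotation.drop_duplicates(subset="gene_id").set_index("gene_id")
    present = adata.var_names.isin(ann.index)
    n_dropped = int((~present).sum())
    if present.sum() == 0:
        raise ValueError(
            "no genes shared between the count matrix "
            f"({adata.n_vars} genes) and the annotation ({len(ann)} entries)"
        )
    if n_dropped:
        logger.info("[preprocess] dropped %d genes without annotation", n_dropped)
    adata = adata[:, present].copy()
    ann = ann.loc[adata.var_names]

    rank = ann["chrom"].map(chromosome_rank)
    placed = rank.notna().to_numpy()
    if (~placed).any():
        logger.warning(
            "[preprocess] dropped %d genes on unplaced contigs", int((~placed).sum())
        )
        adata = adata[:, placed].copy()
        ann = ann.loc[adata.var_names]
        rank = rank[placed]

    adata.var["chrom"] = ann["chrom"].astype(str).to_numpy()
    adata.var["start"] = ann["start"].astype(np.int64).to_numpy()
    adata.var["end"] = ann["end"].astype(np.int64).to_numpy()
    adata.var["chrom_rank"] = rank.astype(int).to_numpy()

    order = np.lexsort(
        (adata.var_names.to_numpy(), adata.var["start"].to_numpy(),
         adata.var["chrom_rank"].to_numpy())
    )
    return adata[:, order].copy()


def qc_filter(adata: ad.AnnData, thresholds: QcThresholds | None = None) -> ad.AnnData:
    """Remove low-quality cells, then genes expressed in no remaining cell.

    A cell fails QC when its total counts are strictly below
    ``min_total_counts``, its number of detected genes is strictly below
    ``min_expressed_genes``, or its mitochondrial count fraction is
    strictly above ``max_mito_fraction``.
    """
    thresholds = thresholds or QcThresholds()
    X = _dense(adata.X)
    totals = X.sum(axis=1)
    n_expressed = (X > 0).sum(axis=1)

    mito_mask = np.array(
        [str(g).upper().startswith("MT-") or str(g).upper() in gene_lists.MITO_GENES
         for g in adata.var_names]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, X[:, mito_mask].sum(axis=1) / totals, 1.0)

    fail_total = totals < thresholds.min_total_counts
    fail_genes = n_expressed < thresholds.min_expressed_genes
    fail_mito = mito_frac > thresholds.max_mito_fraction
    keep = ~(fail_total | fail_genes | fail_mito)

    if not keep.any():
        raise ValueError(
            "QC removed all cells "
            f"(low total counts: {int(fail_total.sum())}, "
            f"few expressed genes: {int(fail_genes.sum())}, "
            f"high mitochondrial fraction: {int(fail_mito.sum())})"
        )
    logger.info(
        "[preprocess] QC removed %d/%d cells (counts %d, genes %d, mito %d)",
        int((~keep).sum()), adata.n_obs, int(fail_total.sum()),
        int(fail_genes.sum()), int(fail_mito.sum()),
    )
    out = adata[keep].copy()

    expressed = _dense(out.X).sum(axis=0) > 0
    n_gene_drop = int((~expressed).sum())
    if n_gene_drop:
        logger.info("[preprocess] removed %d nonexpressed genes", n_gene_drop)
        out = out[:, expressed].copy()
    return out


def exclude_gene_classes(
    adata: ad.AnnData,
    mito_list=gene_lists.MITO_GENES,
    hla_list=gene_lists.HLA_GENES,
    cellcycle_list=gene_lists.CELL_CYCLE_GENES,
) -> ad.AnnData:
    """Drop mitochondrial, HLA and cell-cycle genes.

    Mitochondrial genes are matched by the ``MT-`` prefix
    (case-insensitive) in addition to ``mito_list``.  An empty
    intersection is legal.
    """
    symbols = np.array([str(g).upper() for g in adata.var_names])
    mito = np.char.startswith(symbols, "MT-") | np.isin(
        symbols, [g.upper() for g in mito_list]
    )
    hla = np.isin(symbols, [g.upper() for g in hla_list])
    cc = np.isin(symbols, [g.upper() for g in cellcycle_list])
    drop = mito | hla | cc
    logger.info(
        "[preprocess] excluded %d mito, %d HLA, %d cell-cycle genes",
        int(mito.sum()), int(hla.sum()), int(cc.sum()),
    )
    return adata[:, ~drop].copy()


def normalize_total(adata: ad.AnnData, target_total: float | None = None) -> ad.AnnData:
    """Scale each cell so its total count equals ``target_total``.

    Defaults to the median of per-cell totals, which preserves the
    overall count scale.  Zero-total cells are an error: they should
    have been removed by QC.
    """
    X = _dense(adata.X)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError(
            f"{int((totals <= 0).sum())} cells have zero total counts; run QC first"
        )
    if target_total is None:
        target_total = float(np.median(totals))
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    out = adata.copy()
    out.X = X * (target_total / totals)[:, None]
    out.uns["target_total"] = target_total
    return out


def bin_genes(adata: ad.AnnData, bin_size: int = 25) -> ad.AnnData:
    """Average runs of ``bin_size`` genomically consecutive genes into bins.

    Binning restarts at every chromosome boundary, so no bin ever spans
    two chromosomes.  When a chromosome's gene count is not divisible by
    ``bin_size``, the remainder is merged into the chromosome's last bin
    (bins of ``bin_size`` to ``2*bin_size - 1`` genes at chromosome ends)
    rather than dropped.

    Returns a new AnnData whose ``var`` describes each bin: ``chrom``,
    ``ordinal`` (per-chromosome 0-based bin number), ``n_genes`` and
    ``gene_ids`` (comma-joined member identifiers), plus ``start``/``end``
    base-pair extent of the member genes.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if "chrom_rank" not in adata.var:
        raise ValueError("matrix is not annotated; run annotate_and_sort first")
    ranks = adata.var["chrom_rank"].to_numpy()
    if np.any(np.diff(ranks) < 0):
        raise ValueError("matrix is not genomically sorted")

    X = _dense(adata.X)
    values, records = [], []
    for r in np.unique(ranks):
        idx = np.flatnonzero(ranks == r)
        n_full = max(len(idx) // bin_size, 1)
        bounds = [i * bin_size for i in range(n_full)] + [len(idx)]
        chrom = adata.var["chrom"].iloc[idx[0]]
        for ordinal in range(len(bounds) - 1):
            members = idx[bounds[ordinal]: bounds[ordinal + 1]]
            values.append(X[:, members].mean(axis=1))
            records.append({
                "chrom": chrom,
                "ordinal": ordinal,
                "n_genes": len(members),
                "gene_ids": ",".join(adata.var_names[members]),
                "start": int(adata.var["start"].iloc[members].min()),
                "end": int(adata.var["end"].iloc[members].max()),
            })

    var = pd.DataFrame(records)
    var.index = var["chrom"].astype(str) + ":" + var["ordinal"].astype(str)
    binned = ad.AnnData(
        X=np.column_stack(values), obs=adata.obs.copy(), var=var,
    )
    binned.uns["bin_size"] = bin_size
    return binned


def preprocess_counts(
    adata: ad.AnnData,
    annotation: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    bin_size: int = 25,
    target_total: float | None = None,
) -> ad.AnnData:
    """Full preprocessing chain: annotate/sort, QC, exclusions, normalize, bin."""
    adata = annotate_and_sort(adata, annotation)
    adata = qc_filter(adata, thresholds)
    adata = exclude_gene_classes(adata)
    adata = normalize_total(adata, target_total)
    return bin_genes(adata, bin_size)
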