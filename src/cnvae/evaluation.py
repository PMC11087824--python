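"""Scoring copy-number calls against a reference profile.

Calls made per gene (or per bin) are mapped onto the genomic positions of
the reference profile; positions not covered by any called gene take the
value of the nearest called gene on the same chromosome (distance to gene
midpoint, ties to the lower coordinate).  Four metrics compare the two
positional profiles: Pearson correlation, cosine similarity, and average
positional Manhattan/Euclidean distances (total distance normalized by
the number of positions, so samples of different size are comparable).

Helpers convert integer copies to log2 ratios, categorize calls around a
copy-2 threshold, and flag loss-of-heterozygosity regions from SNP
variant allele frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cosine as cosine_distance
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    pearson: float
    cosine_similarity: float
    avg_manhattan: float
    avg_euclidean: float
    n_positions: int

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "cosine_similarity": self.cosine_similarity,
            "avg_manhattan": self.avg_manhattan,
            "avg_euclidean": self.avg_euclidean,
            "n_positions": self.n_positions,
        }


def map_to_positions(
    gene_calls: pd.DataFrame, eval_positions: pd.DataFrame
) -> pd.DataFrame:
    """Project per-gene calls onto reference genomic positions.

    Parameters
    ----------
    gene_calls
        Columns ``chrom``, ``start``, ``end``, ``value`` — one row per
        called gene (or bin) with its coordinates.
    eval_positions
        Columns ``chrom``, ``pos`` — the positions at which the ground
        truth is defined.

    Returns the eval table with a ``value`` column; positions on
    chromosomes absent from the calls are dropped (count logged).
    """
    out_rows = []
    n_missing = 0
    calls_by_chrom = {c: g.sort_values("start") for c, g in gene_calls.groupby("chrom")}
    for chrom, grp in eval_positions.groupby("chrom"):
        calls = calls_by_chrom.get(chrom)
        if calls is None:
            n_missing += len(grp)
            continue
        starts = calls["start"].to_numpy(dtype=np.float64)
        ends = calls["end"].to_numpy(dtype=np.float64)
        mids = (starts + ends) / 2.0
        vals = calls["value"].to_numpy(dtype=np.float64)
        for pos in grp["pos"].to_numpy(dtype=np.float64):
            inside = np.flatnonzero((starts <= pos) & (pos <= ends))
            if inside.size:
                j = inside[np.argmin(np.abs(mids[inside] - pos))]
            else:
                d = np.abs(mids - pos)
                # ties -> lower coordinate: argmin returns the first, and
                # calls are sorted by start
                j = int(np.argmin(d))
            out_rows.append({"chrom": chrom, "pos": pos, "value": vals[j]})
    if n_missing:
        logger.warning(
            "[evaluation] %d positions on chromosomes without calls excluded",
            n_missing,
        )
    out = pd.DataFrame(out_rows, columns=["chrom", "pos", "value"])
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def score(estimate: np.ndarray, truth: np.ndarray) -> MetricReport:
    """Pearson, cosine similarity and average positional distances."""
    estimate = np.asarray(estimate, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if estimate.shape != truth.shape or estimate.ndim != 1:
        raise ValueError("estimate and truth must be aligned 1-D profiles")
    n = len(estimate)
    if np.std(estimate) == 0 or np.std(truth) == 0:
        warnings.warn("zero-variance profile: Pearson undefined", stacklevel=2)
        pearson = float("nan")
    else:
        pearson = float(pearsonr(estimate, truth).statistic)
    cos = 1.0 - float(cosine_distance(estimate, truth)) \
        if estimate.any() and truth.any() else float("nan")
    diff = estimate - truth
    return MetricReport(
        pearson=pearson,
        cosine_similarity=cos,
        avg_manhattan=float(np.abs(diff).sum() / n),
        avg_euclidean=float(np.sqrt((diff ** 2).sum()) / n),
        n_positions=n,
    )


def to_log2_ratio(copies: np.ndarray, zero_clip: float = 0.1) -> np.ndarray:
    """Integer copies -> log2(c / 2); zero copies clipped to ``zero_clip``."""
    copies = np.asarray(copies, dtype=np.float64)
    if np.any(copies < 0):
        raise ValueError("copy numbers must be non-negative")
    return np.log2(np.maximum(copies, zero_clip) / 2.0)


def categorize_cnv(copies: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Classify copies as 'amplification' (> threshold), 'deletion' (<) or 'neutral'."""
    copies = np.asarray(copies, dtype=np.float64)
    if np.any(copies < 0):
        raise ValueError("copy numbers must be non-negative")
    out = np.full(copies.shape, "neutral", dtype=object)
    out[copies > threshold] = "amplification"
    out[copies < threshold] = "deletion"
    return out


def loh_annotate(vaf_table: pd.DataFrame, categories: pd.DataFrame) -> pd.DataFrame:
    """Loss-of-heterozygosity regions from SNP allele frequencies.

    A position is LoH when its SNP variant allele frequency is extreme
    (< 0.1 or > 0.9, i.e. effectively homozygous) *and* the copy-number
    category there is neutral or deletion — extreme VAF under an
    amplification is explained by unbalanced gain, not allele loss.

    Parameters
    ----------
    vaf_table
        Columns ``chrom``, ``pos``, ``vaf``.
    categories
        Columns ``chrom``, ``pos``, ``category`` aligned by position.

    Returns contiguous LoH runs merged into regions (chrom, start, end).
    """
    vaf = vaf_table["vaf"].to_numpy(dtype=np.float64)
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("VAF values must lie in [0, 1]")
    merged = vaf_table.merge(categories, on=["chrom", "pos"], how="inner")
    merged = merged.sort_values(["chrom", "pos"], kind="stable")
    extreme = (merged["vaf"] < 0.1) | (merged["vaf"] > 0.9)
    eligible = merged["category"].isin(["neutral", "deletion"])
    merged["is_loh"] = (extreme & eligible).to_numpy()

    regions = []
    for chrom, grp in merged.groupby("chrom"):
        run_start = None
        prev = None
        for _, row in grp.iterrows():
            if row["is_loh"]:
                if run_start is None:
                    run_start = row["pos"]
                prev = row["pos"]
            elif run_start is not None:
                regions.append({"chrom": chrom, "start": run_start, "end": prev})
                run_start = None
        if run_start is not None:
            regions.append({"chrom": chrom, "start": run_start, "end": prev})
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])
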