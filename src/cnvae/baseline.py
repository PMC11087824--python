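"""Diploid-cluster identification and pseudo-copy construction.

After stage-1 training, latent cell representations are clustered with
k-means.  One cluster must then be recognised as the diploid (normal)
population without any marker genes.  The working assumption is that
normal cells are less diverse than tumour cells.

Two per-cluster "auto-correlation" scores are provided:

* ``"genomic"`` (default) — mean over member cells of the lag-1 Pearson
  autocorrelation of the cell's bin profile along the genome, computed
  within chromosomes and averaged.  A diploid cell's profile has no CNV
  blocks, so neighbouring bins fluctuate independently and the score
  sits at the noise floor, while multi-bin copy-number events induce
  strong positive autocorrelation in aneuploid cells.  The diploid
  cluster is therefore the one whose *genomic smoothness is lowest*:
  selection maximises the negated score.
* ``"coherence"`` — mean Pearson correlation between each member cell's
  bin profile and the cluster's mean profile, a direct diversity
  measure (homogeneous clusters score high); selection maximises it.
  Shared CNV event *locations* also raise the coherence of aneuploid
  clusters, which makes this variant less discriminative when the
  tumour fraction dominates; it is kept as an alternative selector.

The baseline expression profile is the per-bin mean over diploid cells;
the pseudo copy matrix is ``2 * expression / baseline`` so that diploid
cells sit at copy 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """k-means labels plus (optionally) the identified diploid cluster."""

    labels: np.ndarray
    k: int
    diploid_cluster: int | None = None

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def cluster_latent(latent: np.ndarray, k: int = 4, seed: int = 0) -> ClusterAssignment:
    """k-means over latent means with multiple restarts; seeded.

    Empty clusters are relabelled away, so every returned cluster id in
    ``[0, k)`` is non-empty (k shrinks if k-means leaves a cluster empty).
    """
    latent = np.asarray(latent, dtype=np.float64)
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = np.unique(latent, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct latent points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(latent)
    # compact labels: drop ids with no members (possible on degenerate data)
    ids = np.unique(raw)
    remap = {old: new for new, old in enumerate(ids)}
    labels = np.array([remap[l] for l in raw])
    return ClusterAssignment(labels=labels, k=len(ids))


def _lag1_autocorr(profile: np.ndarray, chrom_ids: np.ndarray) -> float:
    """Lag-1 Pearson autocorrelation within chromosomes, averaged.

    Zero-variance (constant) stretches contribute 0 by convention.
    """
    vals = []
    for c in np.unique(chrom_ids):
        x = profile[chrom_ids == c]
        if len(x) < 3:
            continue
        a, b = x[:-1], x[1:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            vals.append(0.0)
        else:
            vals.append(float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)))
    return float(np.mean(vals)) if vals else 0.0


def autocorrelation_score(
    binned: np.ndarray,
    assignment: ClusterAssignment,
    chrom_ids: np.ndarray | None = None,
    mode: str = "genomic",
) -> dict[int, float]:
    """Per-cluster score used to recognise the diploid population.

    Parameters
    ----------
    binned
        Cells x bins matrix (genomically ordered bins).
    assignment
        Output of :func:`cluster_latent`.
    chrom_ids
        Per-bin chromosome identifiers; required for ``mode="genomic"``.
    mode
        ``"coherence"`` or ``"genomic"`` (see module docstring).
    """
    binned = np.asarray(binned, dtype=np.float64)
    scores: dict[int, float] = {}
    for cid in range(assignment.k):
        rows = binned[assignment.members(cid)]
        if mode == "genomic":
            if chrom_ids is None:
                raise ValueError("mode='genomic' requires chrom_ids")
            scores[cid] = float(
                np.mean([_lag1_autocorr(r, np.asarray(chrom_ids)) for r in rows])
            )
        elif mode == "coherence":
            center = rows.mean(axis=0)
            cs = center.std()
            vals = []
            for r in rows:
                rs = r.std()
                vals.append(
                    0.0 if rs == 0 or cs == 0 else
                    float(np.mean((r - r.mean()) * (center - center.mean())) / (rs * cs))
                )
            scores[cid] = float(np.mean(vals))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return scores


def select_diploid(scores: dict[int, float], sizes: dict[int, int]) -> int:
    """Cluster with the greatest score; ties -> larger cluster, then lower id."""
    if len(scores) < 2:
        raise ValueError("need scores for at least two clusters")
    best = max(scores, key=lambda c: (scores[c], sizes[c], -c))
    logger.info("[baseline] diploid cluster %d (score %.4f, %d cells)",
                best, scores[best], sizes[best])
    return best


def baseline_profile(binned: np.ndarray, diploid_cells: np.ndarray) -> np.ndarray:
    """Per-bin mean expression over the identified diploid cells.

    Zero bins are floored to 0.1x the smallest positive baseline value so
    the profile can be used as a divisor without dropping bins; floored
    bins are logged.
    """
    binned = np.asarray(binned, dtype=np.float64)
    diploid_cells = np.asarray(diploid_cells)
    if diploid_cells.dtype == bool:
        diploid_cells = np.flatnonzero(diploid_cells)
    if len(diploid_cells) == 0:
        raise ValueError(
            "no diploid cells identified; the method requires normal cells "
            "in the population and degrades without them"
        )
    profile = binned[diploid_cells].mean(axis=0)
    zero = profile <= 0
    if zero.any():
        positive = profile[~zero]
        if positive.size == 0:
            raise ValueError("baseline profile is zero everywhere")
        floor = 0.1 * positive.min()
        profile = np.where(zero, floor, profile)
        logger.warning("[baseline] floored %d zero baseline bins to %.3g",
                       int(zero.sum()), floor)
    return profile


def pseudo_copy(binned: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Preliminary copy estimates: ``2 * expression / baseline`` per bin."""
    binned = np.asarray(binned, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.ndim != 1 or baseline.shape[0] != binned.shape[1]:
        raise ValueError(
            f"baseline length {baseline.shape} does not match "
            f"{binned.shape[1]} bins"
        )
    if np.any(baseline <= 0):
        raise ValueError("baseline must be strictly positive")
    return 2.0 * binned / baseline[None, :]


@dataclass
class DiploidResult:
    """Everything stage 1 derives from the latent space."""

    assignment: ClusterAssignment
    scores: dict[int, float]
    baseline: np.ndarray
    pseudo: np.ndarray
    diploid_mask: np.ndarray = field(default=None)


def identify_diploid(
    latent: np.ndarray,
    binned: np.ndarray,
    chrom_ids: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
    score_mode: str = "genomic",
) -> DiploidResult:
    """Cluster latents, pick the diploid cluster, build baseline and pseudo copies.

    Under the default ``"genomic"`` score the diploid cluster is the one
    with the *least* genomic autocorrelation (flattest copy structure),
    so its negated score is handed to :func:`select_diploid`; the
    ``"coherence"`` score is maximised directly.
    """
    assignment = cluster_latent(latent, k=k, seed=seed)
    scores = autocorrelation_score(binned, assignment, chrom_ids, mode=score_mode)
    diploidy = {c: -s for c, s in scores.items()} if score_mode == "genomic" else scores
    sizes = {c: int((assignment.labels == c).sum()) for c in range(assignment.k)}
    assignment.diploid_cluster = select_diploid(diploidy, sizes)
    mask = assignment.labels == assignment.diploid_cluster
    base = baseline_profile(binned, np.flatnonzero(mask))
    pc = pseudo_copy(binned, base)
    return DiploidResult(
        assignment=assignment, scores=scores, baseline=base, pseudo=pc,
        diploid_mask=mask,
    )
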