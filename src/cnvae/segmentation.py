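"""Likelihood-based segmentation of copy-ratio tracks and profile calling.

Breakpoints are found per tumour clone on the clone-mean refined copy
track with greedy binary segmentation under a Gaussian likelihood: a
candidate split of a segment is accepted when twice the log-likelihood
gain exceeds ``penalty * log(n_bins)`` (a BIC-style cost per breakpoint),
and accepted segments are split recursively.  Chromosomes are segmented
independently, so breakpoints never cross chromosome boundaries.

The noise scale entering the likelihood is estimated robustly from the
median absolute deviation of first differences of the track, which is
insensitive to the change points being sought.

Per-cell integer profiles take the median of the cell's refined bin
values inside each clone segment, rounded half-away-from-zero and
clipped to ``[0, max_cn]``; the clone profile is the per-segment mean of
its members' integer copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class BreakpointSet:
    """Per-chromosome ordered breakpoint bin indices (segment starts, 0-based).

    ``breakpoints[chrom]`` lists interior breakpoints only; 0 and the
    chromosome length are implicit boundaries.
    """

    breakpoints: dict = field(default_factory=dict)
    chrom_sizes: dict = field(default_factory=dict)

    def segments(self, chrom) -> list[tuple[int, int]]:
        """Half-open (start, end) bin segments for one chromosome."""
        bps = self.breakpoints.get(chrom, [])
        bounds = [0] + list(bps) + [self.chrom_sizes[chrom]]
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def estimate_sigma(track: np.ndarray) -> float:
    """Robust noise scale from first differences (MAD-based).

    ``diff`` of i.i.d. N(m, sigma^2) noise has scale ``sigma * sqrt(2)``;
    the MAD ignores the few large jumps at true change points.
    """
    track = np.asarray(track, dtype=np.float64)
    if len(track) < 2:
        return 1.0
    d = np.diff(track)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad * 1.4826 / np.sqrt(2.0)
    return max(float(sigma), 1e-4)


def _sse(prefix, prefix2, lo, hi):
    """Sum of squared deviations from the mean of track[lo:hi]."""
    n = hi - lo
    s = prefix[hi] - prefix[lo]
    s2 = prefix2[hi] - prefix2[lo]
    return max(s2 - s * s / n, 0.0)


def _binary_segment(track, penalty_cost, sigma):
    """Greedy recursive binary segmentation of one chromosome track."""
    n = len(track)
    prefix = np.concatenate([[0.0], np.cumsum(track)])
    prefix2 = np.concatenate([[0.0], np.cumsum(track ** 2)])
    result = []

    def split(lo, hi):
        if hi - lo < 2:
            return
        base = _sse(prefix, prefix2, lo, hi)
        gains = np.array([
            base - _sse(prefix, prefix2, lo, t) - _sse(prefix, prefix2, t, hi)
            for t in range(lo + 1, hi)
        ])
        t_best = int(np.argmax(gains)) + lo + 1
        # 2 * (ll_split - ll_joint) with known sigma
        if gains[t_best - lo - 1] / sigma ** 2 > penalty_cost:
            split(lo, t_best)
            result.append(t_best)
            split(t_best, hi)

    split(0, n)
    return sorted(result)


def find_breakpoints(
    track: np.ndarray,
    chrom_ids: np.ndarray,
    penalty: float = 3.0,
    sigma: float | None = None,
) -> BreakpointSet:
    """Change points of a clone-mean bin track, per chromosome.

    Parameters
    ----------
    track
        1-D refined copy track over genomically ordered bins.
    chrom_ids
        Per-bin chromosome identifier, same length as ``track``.
    penalty
        Multiplier on ``log(n_bins_in_chromosome)``; a split is accepted
        when the likelihood-ratio statistic exceeds ``penalty * log(n)``.
    sigma
        Known noise scale; estimated robustly per chromosome if None.
    """
    track = np.asarray(track, dtype=np.float64)
    chrom_ids = np.asarray(chrom_ids)
    if track.ndim != 1 or track.shape != chrom_ids.shape:
        raise ValueError("track and chrom_ids must be 1-D and aligned")
    bset = BreakpointSet()
    for c in pd_unique(chrom_ids):
        mask = chrom_ids == c
        x = track[mask]
        bset.chrom_sizes[c] = int(mask.sum())
        if len(x) < 2:
            bset.breakpoints[c] = []
            continue
        s = sigma if sigma is not None else estimate_sigma(x)
        cost = penalty * np.log(len(x))
        bset.breakpoints[c] = _binary_segment(x, cost, s)
    return bset


def pd_unique(values):
    """Unique values in order of first appearance (chromosome order)."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (2.5 -> 3), unlike numpy's banker's rounding."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def segment_cell_profile(
    cell_track: np.ndarray,
    chrom_ids: np.ndarray,
    breakpoints: BreakpointSet,
    max_cn: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment median copies for one cell, expanded back to bins.

    Returns ``(per_bin_integer, per_bin_real)``: the integer profile
    (median rounded half-away-from-zero, clipped to ``[0, max_cn]``)
    expanded so each bin carries its segment's value, and the unrounded
    segment medians expanded the same way.
    """
    cell_track = np.asarray(cell_track, dtype=np.float64)
    chrom_ids = np.asarray(chrom_ids)
    out_int = np.empty_like(cell_track)
    out_real = np.empty_like(cell_track)
    offset = 0
    for c in pd_unique(chrom_ids):
        n = int((chrom_ids == c).sum())
        x = cell_track[offset:offset + n]
        for lo, hi in breakpoints.segments(c):
            med = float(np.median(x[lo:hi]))
            out_real[offset + lo: offset + hi] = med
            out_int[offset + lo: offset + hi] = np.clip(
                round_half_away(med), 0, max_cn
            )
        offset += n
    return out_int, out_real


def clone_profile(cell_profiles: np.ndarray) -> np.ndarray:
    """Mean per-bin copy over a clone's member cells (real-valued)."""
    cell_profiles = np.asarray(cell_profiles, dtype=np.float64)
    if cell_profiles.ndim != 2 or cell_profiles.shape[0] == 0:
        raise ValueError("need a non-empty cells x bins matrix")
    return cell_profiles.mean(axis=0)


def assign_clones(labels: np.ndarray, diploid_cluster: int) -> dict[int, np.ndarray]:
    """Clones = non-diploid k-means clusters; maps clone id -> member indices."""
    labels = np.asarray(labels)
    clones = {
        int(c): np.flatnonzero(labels == c)
        for c in np.unique(labels) if c != diploid_cluster
    }
    if not clones:
        logger.warning("[segmentation] no aneuploid cells: all-normal sample")
    return clones
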