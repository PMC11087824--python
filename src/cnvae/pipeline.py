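"""End-to-end copy-number inference: the two-stage workflow as one estimator.

``CopyNumberPipeline`` consumes the preprocessed cells x bins expression
matrix and runs:

1. stage-1 VAE (negative-binomial likelihood) -> latent representation;
2. k-means on the latents; the cluster whose profiles are flattest along
   the genome (least lag-1 autocorrelation) is taken as the diploid
   population;
3. baseline profile from diploid cells -> pseudo copy matrix
   (``2 * expression / baseline``);
4. stage-2 VAE (Gaussian likelihood) on the pseudo copies -> refined
   per-bin copy estimates;
5. per-clone breakpoint calling on the clone-mean refined track, segment
   medians per cell, integer rounding, and clone-mean profiles.

Diploid cells are reported as copy 2 everywhere.  All randomness flows
from ``random_state``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from sklearn.base import BaseEstimator

from . import baseline as baseline_mod
from . import segmentation as seg_mod
from .preprocess import QcThresholds, preprocess_counts
from .vae import CountVAE

logger = logging.getLogger(__name__)


class CopyNumberPipeline(BaseEstimator):
    """Two-stage VAE copy-number caller over a binned expression matrix.

    Parameters
    ----------
    k : int
        Number of k-means clusters over the stage-1 latent space; the
        non-diploid clusters become the tumour clones.
    latent_dim, hidden_dim, epochs, batch_size, learning_rate, kl_weight
        Shared VAE hyperparameters for both stages.
    penalty : float
        Segmentation penalty multiplier on ``log(n_bins)``.
    max_cn : int
        Copy numbers are clipped to ``[0, max_cn]``.
    score_mode : {"coherence", "genomic"}
        Per-cluster score used to recognise the diploid cluster.
    random_state : int
        Master seed for both VAEs and k-means.

    Attributes (after ``fit``)
    --------------------------
    labels_ : per-cell k-means cluster id
    diploid_cluster_, diploid_mask_ : identified normal population
    baseline_ : per-bin diploid expression profile
    pseudo_ : cells x bins pseudo copy matrix
    refined_ : cells x bins stage-2 refined copies
    breakpoints_ : clone id -> BreakpointSet
    cell_profiles_ : cells x bins integer copies (diploid rows = 2)
    clone_profiles_ : clone id -> per-bin mean copy profile
    tumour_profile_ : cell-weighted mean profile over all aneuploid cells
    """

    def __init__(
        self,
        k: int = 5,
        latent_dim: int = 10,
        hidden_dim: int = 128,
        epochs: int = 200,
        batch_size: int = 128,
        learning_rate: float = 1e-3,
        kl_weight: float = 1.0,
        penalty: float = 3.0,
        max_cn: int = 6,
        score_mode: str = "genomic",
        random_state: int = 0,
    ):
        self.k = k
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.kl_weight = kl_weight
        self.penalty = penalty
        self.max_cn = max_cn
        self.score_mode = score_mode
        self.random_state = random_state

    def _vae(self, likelihood: str, seed_offset: int) -> CountVAE:
        return CountVAE(
            latent_dim=self.latent_dim,
            hidden_dim=self.hidden_dim,
            likelihood=likelihood,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            kl_weight=self.kl_weight,
            random_state=self.random_state + seed_offset,
        )

    def fit(self, X, chrom_ids=None):
        """Run the full workflow on a cells x bins matrix.

        ``chrom_ids`` gives each bin's chromosome (required: segmentation
        is per-chromosome).  ``X`` may be an AnnData from the
        preprocessing binner, in which case chromosome ids are taken from
        ``X.var["chrom"]``.
        """
        if isinstance(X, ad.AnnData):
            if chrom_ids is None:
                chrom_ids = X.var["chrom"].to_numpy()
            X = np.asarray(X.X, dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if chrom_ids is None:
            raise ValueError("chrom_ids are required (per-bin chromosome labels)")
        chrom_ids = np.asarray(chrom_ids)
        n_cells, n_bins = X.shape

        t0 = time.time()
        self.stage1_ = self._vae("nb", 0).fit(X)
        latent = self.stage1_.transform(X)
        logger.info("[pipeline] stage-1 VAE done (%.1fs)", time.time() - t0)

        res = baseline_mod.identify_diploid(
            latent, X, chrom_ids, k=self.k, seed=self.random_state + 1,
            score_mode=self.score_mode,
        )
        self.latent_ = latent
        self.labels_ = res.assignment.labels
        self.diploid_cluster_ = res.assignment.diploid_cluster
        self.diploid_mask_ = res.diploid_mask
        self.cluster_scores_ = res.scores
        self.baseline_ = res.baseline
        self.pseudo_ = res.pseudo

        t0 = time.time()
        self.stage2_ = self._vae("gaussian", 2).fit(self.pseudo_)
        self.refined_ = self.stage2_.reconstruct(self.pseudo_)
        logger.info("[pipeline] stage-2 VAE done (%.1fs)", time.time() - t0)

        clones = seg_mod.assign_clones(self.labels_, self.diploid_cluster_)
        self.clones_ = clones
        self.breakpoints_ = {}
        self.clone_profiles_ = {}
        cell_profiles = np.full((n_cells, n_bins), 2.0)
        cell_profiles_real = np.full((n_cells, n_bins), 2.0)
        for cid, members in clones.items():
            track = self.refined_[members].mean(axis=0)
            bset = seg_mod.find_breakpoints(track, chrom_ids, penalty=self.penalty)
            self.breakpoints_[cid] = bset
            profiles = []
            for cell in members:
                prof_int, prof_real = seg_mod.segment_cell_profile(
                    self.refined_[cell], chrom_ids, bset, max_cn=self.max_cn
                )
                cell_profiles[cell] = prof_int
                cell_profiles_real[cell] = prof_real
                profiles.append(prof_int)
            self.clone_profiles_[cid] = seg_mod.clone_profile(np.array(profiles))

        self.cell_profiles_ = cell_profiles.astype(np.int64)
        self.cell_profiles_real_ = cell_profiles_real
        aneuploid = ~self.diploid_mask_
        self.tumour_profile_ = (
            cell_profiles[aneuploid].mean(axis=0) if aneuploid.any() else None
        )
        self.chrom_ids_ = chrom_ids
        self.n_features_in_ = n_bins
        return self

    def predict(self, X=None):
        """Per-cell integer copy profiles from the fitted run."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "cell_profiles_")
        return self.cell_profiles_


# ----------------------------------------------------------------------
# file-level orchestration
# ----------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths plus every tunable of a full run (serialized into the manifest)."""

    input_path: str
    annotation_path: str
    out_dir: str
    qc: QcThresholds = field(default_factory=QcThresholds)
    bin_size: int = 25
    k: int = 5
    latent_dim: int = 10
    hidden_dim: int = 128
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    kl_weight: float = 1.0
    penalty: float = 3.0
    max_cn: int = 6
    score_mode: str = "genomic"
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Preprocess, fit the pipeline, write all outputs plus a run manifest."""
    from . import io as io_mod
    from . import __version__

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_times = {}
    counts_record = {}

    t0 = time.time()
    adata = io_mod.read_counts(config.input_path)
    annotation = io_mod.read_annotation(config.annotation_path)
    counts_record["cells_in"], counts_record["genes_in"] = adata.shape
    stage_times["read"] = time.time() - t0

    t0 = time.time()
    binned = preprocess_counts(
        adata, annotation, thresholds=config.qc, bin_size=config.bin_size
    )
    counts_record["cells_kept"], counts_record["bins"] = binned.shape
    stage_times["preprocess"] = time.time() - t0

    t0 = time.time()
    pipe = CopyNumberPipeline(
        k=config.k, latent_dim=config.latent_dim, hidden_dim=config.hidden_dim,
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, kl_weight=config.kl_weight,
        penalty=config.penalty, max_cn=config.max_cn,
        score_mode=config.score_mode, random_state=config.seed,
    )
    pipe.fit(binned)
    stage_times["fit"] = time.time() - t0

    t0 = time.time()
    bin_names = list(binned.var_names)
    cells = list(binned.obs_names)
    files = {}

    labels = pd.DataFrame({
        "cell_id": cells,
        "cluster": pipe.labels_,
        "is_diploid": pipe.diploid_mask_.astype(int),
    })
    files["clusters"] = out_dir / "clusters.tsv"
    labels.to_csv(files["clusters"], sep="\t", index=False)

    files["baseline"] = out_dir / "baseline.tsv"
    pd.DataFrame({"bin": bin_names, "value": pipe.baseline_}).to_csv(
        files["baseline"], sep="\t", index=False
    )
    files["pseudo_copy"] = io_mod.write_matrix_tsv(
        pipe.pseudo_, cells, bin_names, out_dir / "pseudo_copy.tsv")
    files["refined_copy"] = io_mod.write_matrix_tsv(
        pipe.refined_, cells, bin_names, out_dir / "refined_copy.tsv")
    files["cell_profiles"] = io_mod.write_matrix_tsv(
        pipe.cell_profiles_, cells, bin_names, out_dir / "cell_profiles.tsv")

    bp_rows = []
    for cid, bset in pipe.breakpoints_.items():
        for chrom, bps in bset.breakpoints.items():
            for b in bps:
                bp_rows.append({"clone": cid, "chrom": chrom, "bin": b})
    files["breakpoints"] = out_dir / "breakpoints.tsv"
    pd.DataFrame(bp_rows, columns=["clone", "chrom", "bin"]).to_csv(
        files["breakpoints"], sep="\t", index=False
    )

    clone_rows = []
    var = binned.var
    for cid, profile in pipe.clone_profiles_.items():
        for b, copy in enumerate(profile):
            clone_rows.append({
                "chrom": var["chrom"].iloc[b],
                "start_bp": int(var["start"].iloc[b]),
                "end_bp": int(var["end"].iloc[b]),
                "clone_id": cid,
                "copy": copy,
            })
    files["clone_profiles"] = out_dir / "clone_profiles.tsv"
    pd.DataFrame(
        clone_rows, columns=["chrom", "start_bp", "end_bp", "clone_id", "copy"]
    ).to_csv(files["clone_profiles"], sep="\t", index=False)

    files["binned"] = io_mod.write_matrix_tsv(
        np.asarray(binned.X), cells, bin_names, out_dir / "binned_matrix.tsv")
    stage_times["write"] = time.time() - t0

    manifest = {
        "version": __version__,
        "config": {
            **{k: v for k, v in config.__dict__.items() if k != "qc"},
            "qc": config.qc.__dict__,
        },
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "counts": counts_record,
        "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
    }
    manifest_path = out_dir / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(manifest_path)
    logger.info("[pipeline] run complete: %s", manifest_path)
    return manifest
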