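import numpy as np
import pytest

from cnvae import preprocess as pp
from cnvae import simulate as sim


def small_qc_thresholds() -> pp.QcThresholds:
    """QC cutoffs scaled to the simulated fixtures' sequencing depth."""
    return pp.QcThresholds(min_total_counts=500, min_expressed_genes=100)


def small_sim_config(seed: int = 0) -> sim.SimConfig:
    """Tiny simulation for plumbing tests (shapes, determinism, I/O)."""
    return sim.SimConfig(
        n_cells=120,
        n_genes=1000,
        n_chromosomes=4,
        n_events=3,
        event_length_bins=(3, 6),
        seed=seed,
    )


def medium_sim_config(seed: int = 0) -> sim.SimConfig:
    """Mid-scale simulation with enough signal for population separation."""
    return sim.SimConfig(
        n_cells=300,
        n_genes=3000,
        n_chromosomes=6,
        n_events=5,
        event_length_bins=(6, 15),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One tiny simulated dataset: (adata, truth_genes, event_set, config)."""
    cfg = small_sim_config()
    adata, truth, events = sim.simulate_dataset(cfg)
    return adata, truth, events, cfg


@pytest.fixture(scope="session")
def small_binned(small_dataset):
    """Preprocessed cells x bins matrix of the tiny dataset."""
    adata, truth, events, cfg = small_dataset
    binned = pp.preprocess_counts(
        adata, sim.make_annotation(cfg), thresholds=small_qc_thresholds()
    )
    return binned


@pytest.fixture(scope="session")
def medium_fixture():
    """Mid-scale dataset bundle: (adata, truth_genes, event_set, config,
    binned, is_aneuploid, truth_bins)."""
    cfg = medium_sim_config()
    adata, truth, events = sim.simulate_dataset(cfg)
    binned = pp.preprocess_counts(
        adata, sim.make_annotation(cfg), thresholds=small_qc_thresholds()
    )
    kept = [adata.obs_names.get_loc(c) for c in binned.obs_names]
    labels = adata.obs["is_aneuploid"].to_numpy()[kept]
    bin_gene_ids = [g.split(",") for g in binned.var["gene_ids"]]
    truth_bins = sim.bin_truth(truth[kept], adata.var_names.to_numpy(), bin_gene_ids)
    return adata, truth, events, cfg, binned, labels, truth_bins


@pytest.fixture(scope="session")
def medium_pipeline(medium_fixture):
    """The full workflow fitted once on the medium fixture."""
    from cnvae import CopyNumberPipeline

    binned = medium_fixture[4]
    return CopyNumberPipeline(random_state=0).fit(binned)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
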