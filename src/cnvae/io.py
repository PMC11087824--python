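"""Reading count matrices and annotations; writing pipeline outputs."""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy.io import mmread

logger = logging.getLogger(__name__)


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir_path}")


def read_counts(path) -> ad.AnnData:
    """Read a cells x genes count matrix.

    Accepts either a 10x-convention directory (``matrix.mtx`` with genes
    as rows and cells as columns, plus ``features.tsv``/``genes.tsv`` and
    ``barcodes.tsv``, optionally gzipped) or a dense TSV.  A dense TSV is
    assumed to be cells x genes when it has at least as many columns as
    rows, genes x cells otherwise (genes almost always outnumber cells);
    the orientation used is logged.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find(path, "matrix.mtx")
        try:
            features = _find(path, "features.tsv")
        except FileNotFoundError:
            features = _find(path, "genes.tsv")
        barcodes = _find(path, "barcodes.tsv")
        X = mmread(str(mtx)).tocsr()
        feat = pd.read_csv(features, sep="\t", header=None)
        bars = pd.read_csv(barcodes, sep="\t", header=None)
        adata = ad.AnnData(
            X=X.T.toarray(),
            obs=pd.DataFrame(index=bars[0].astype(str)),
            var=pd.DataFrame(index=feat[0].astype(str)),
        )
        return adata

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] > df.shape[1]:
        logger.info("[io] dense TSV interpreted as genes x cells (transposing)")
        df = df.T
    return ad.AnnData(
        X=df.to_numpy(dtype=np.float64),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV: gene_id, chrom, start, end (header optional)."""
    path = Path(path)
    first = _open_maybe_gz(path).readline().split("\t")
    has_header = not (len(first) >= 4 and first[2].strip().isdigit())
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None,
        usecols=range(4),
    )
    df.columns = ["gene_id", "chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] > df["end"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} annotation rows have start > end")
    return df


def write_matrix_tsv(values: np.ndarray, row_names, col_names, path) -> Path:
    path = Path(path)
    pd.DataFrame(values, index=row_names, columns=col_names).to_csv(path, sep="\t")
    return path


def write_counts_10x(adata: ad.AnnData, out_dir) -> dict[str, Path]:
    """Write counts as plain MatrixMarket + features/barcodes TSVs."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    mmwrite(str(paths["matrix"]), csr_matrix(np.asarray(X).T))
    pd.Series(adata.var_names).to_csv(paths["features"], sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t",
                                      index=False, header=False)
    return paths
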