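"""Reading and writing datasets as MTX counts with TSV sidecars.

On disk a dataset is ``<prefix>_matrix.mtx`` (MatrixMarket, 1-based
coordinates, spots/nuclei as rows), ``<prefix>_obs.tsv`` and
``<prefix>_var.tsv``. Internal indexing is 0-based throughout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse


def write_dataset(adata: AnnData, outdir, prefix: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    spio.mmwrite(outdir / f"{prefix}_matrix.mtx", X.astype(int))
    adata.obs.to_csv(outdir / f"{prefix}_obs.tsv", sep="\t")
    adata.var.to_csv(outdir / f"{prefix}_var.tsv", sep="\t")


def read_dataset(outdir, prefix: str) -> AnnData:
    outdir = Path(outdir)
    X = sparse.csr_matrix(spio.mmread(outdir / f"{prefix}_matrix.mtx"))
    obs = pd.read_csv(outdir / f"{prefix}_obs.tsv", sep="\t", index_col=0)
    var = pd.read_csv(outdir / f"{prefix}_var.tsv", sep="\t", index_col=0)
    for col in ("mitochondrial", "lncRNA", "pseudogene"):
        if col in var.columns:
            var[col] = var[col].astype(bool)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return AnnData(X=X, obs=obs, var=var)
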