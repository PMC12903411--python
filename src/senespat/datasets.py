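"""Dataset containers and schema.

Spatial and single-nucleus datasets are plain :class:`anndata.AnnData`
objects with a fixed metadata schema, following the scanpy convention of
functions-over-AnnData rather than bespoke container classes.

Spatial dataset (spot x gene)
    ``obs``: ``array_id``, ``donor_id``, ``age_group`` (young/middle/old),
    ``sex`` (M/F), ``row``, ``col`` (integer grid coordinates), ``aar``
    (one of L1..L6, WM, or "none" for unannotated spots).
    ``var``: ``symbol``, boolean flags ``mitochondrial``, ``lncRNA``,
    ``pseudogene``.

Nuclei dataset (nucleus x gene)
    ``obs``: ``donor_id``, ``batch``, ``age`` (years), ``age_group``,
    ``sex``, ``broad_class`` (one of 8 classes), ``subcluster``,
    ``n_umi``, ``mt_frac``.
    ``var``: as above.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData

#: Anatomical annotation regions: six cortical layers plus white matter.
AARS = ("L1", "L2", "L3", "L4", "L5", "L6", "WM")

#: Label for spots without a valid anatomical annotation.
AAR_NONE = "none"

#: Donor age-group vocabulary (young <45, middle 45-55, old >55 years).
AGE_GROUPS = ("young", "middle", "old")

#: Broad cell classes of the cortical single-nucleus data.
BROAD_CLASSES = ("Ast", "End", "Exc", "Inh", "Mic", "Oli", "OPC", "Peri")

SPATIAL_OBS_COLUMNS = ("array_id", "donor_id", "age_group", "sex", "row", "col", "aar")
NUCLEI_OBS_COLUMNS = (
    "donor_id",
    "batch",
    "age",
    "age_group",
    "sex",
    "broad_class",
    "subcluster",
    "n_umi",
    "mt_frac",
)
VAR_COLUMNS = ("symbol", "mitochondrial", "lncRNA", "pseudogene")


def counts_matrix(adata: AnnData) -> np.ndarray:
    """Return the raw counts of ``adata`` as a dense float array."""
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def validate_spatial(adata: AnnData) -> None:
    """Check the spatial schema; raise ``ValueError`` on violation."""
    _check_columns(adata, SPATIAL_OBS_COLUMNS, VAR_COLUMNS)
    _check_counts(adata)
    aar = set(adata.obs["aar"].astype(str))
    allowed = set(AARS) | {AAR_NONE}
    if not aar <= allowed:
        raise ValueError(f"unknown AAR labels: {sorted(aar - allowed)}")
    groups = set(adata.obs["age_group"].astype(str))
    if not groups <= set(AGE_GROUPS):
        raise ValueError(f"unknown age groups: {sorted(groups - set(AGE_GROUPS))}")


def validate_nuclei(adata: AnnData) -> None:
    """Check the nuclei schema; raise ``ValueError`` on violation."""
    _check_columns(adata, NUCLEI_OBS_COLUMNS, VAR_COLUMNS)
    _check_counts(adata)
    n_umi = np.asarray(adata.obs["n_umi"], dtype=float)
    row_sums = counts_matrix(adata).sum(axis=1)
    if not np.allclose(n_umi, row_sums):
        raise ValueError("obs['n_umi'] does not equal the row sums of the counts")
    mt = np.asarray(adata.obs["mt_frac"], dtype=float)
    if np.any((mt < 0) | (mt > 1)):
        raise ValueError("mt_frac outside [0, 1]")


def _check_columns(adata: AnnData, obs_cols, var_cols) -> None:
    missing = [c for c in obs_cols if c not in adata.obs.columns]
    if missing:
        raise ValueError(f"missing obs columns: {missing}")
    missing = [c for c in var_cols if c not in adata.var.columns]
    if missing:
        raise ValueError(f"missing var columns: {missing}")


def _check_counts(adata: AnnData) -> None:
    X = counts_matrix(adata)
    if X.size and (np.any(X < 0) or np.any(X != np.floor(X))):
        raise ValueError("counts must be non-negative integers")


def make_var(symbols, mitochondrial=None, lncRNA=None, pseudogene=None) -> pd.DataFrame:
    """Assemble a ``var`` table from symbols and optional biotype flags."""
    n = len(symbols)

    def flags(x):
        if x is None:
            return np.zeros(n, dtype=bool)
        return np.asarray(x, dtype=bool)

    return pd.DataFrame(
        {
            "symbol": list(symbols),
            "mitochondrial": flags(mitochondrial),
            "lncRNA": flags(lncRNA),
            "pseudogene": flags(pseudogene),
        },
        index=pd.Index([str(s) for s in symbols], name="gene"),
    )
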