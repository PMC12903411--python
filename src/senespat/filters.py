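"""Gene, spot, and nucleus quality filters.

Spatial filtering removes mitochondrial/lncRNA/pseudogene biotypes and
genes detected in fewer than 0.67% of spots, then discards spots with
fewer than 100 UMIs over the remaining genes, spots without a valid
anatomical annotation, and spots left without a grid neighbor (iterated
to a fixed point, since removing a spot can isolate its neighbors and an
isolated spot would make the spatial autocorrelation prior singular).
Nuclei QC keeps nuclei with nUMI > 500 (strict) and mitochondrial
fraction < 5% (strict), then drops the mitochondrial genes.
"""

from __future__ import annotations

import logging

import numpy as np
from anndata import AnnData

from ._grid import edges_from_coords
from .datasets import AAR_NONE, counts_matrix

logger = logging.getLogger(__name__)


def filter_genes(ds: AnnData, min_spot_fraction: float = 0.0067) -> AnnData:
    """Drop flagged biotypes and genes detected in too few spots.

    A gene is detected in a spot if its count is > 0; it survives when it
    is detected in at least ``min_spot_fraction`` of spots and carries
    none of the mitochondrial/lncRNA/pseudogene flags. Gene order is
    preserved.
    """
    X = counts_matrix(ds)
    flagged = (
        ds.var["mitochondrial"].to_numpy()
        | ds.var["lncRNA"].to_numpy()
        | ds.var["pseudogene"].to_numpy()
    )
    detect_frac = (X > 0).mean(axis=0)
    rare = detect_frac < min_spot_fraction
    keep = ~flagged & ~rare
    if not keep.any():
        raise ValueError(
            f"no genes survive: {int(flagged.sum())} flagged biotypes, "
            f"{int(rare.sum())} below detection fraction {min_spot_fraction}"
        )
    logger.info(
        "filter_genes: %d flagged biotype, %d below %.4f detection, %d kept",
        int(flagged.sum()),
        int((rare & ~flagged).sum()),
        min_spot_fraction,
        int(keep.sum()),
    )
    return ds[:, keep].copy()


def filter_spots(ds: AnnData, min_umi: int = 100) -> AnnData:
    """Drop low-depth, unannotated, and isolated spots.

    Keeps spots with UMI >= ``min_umi`` over the current genes and a
    valid AAR label, then iteratively removes spots with no surviving
    rook neighbor within their array until stable.
    """
    umi = counts_matrix(ds).sum(axis=1)
    annotated = (ds.obs["aar"].astype(str) != AAR_NONE).to_numpy()
    keep = (umi >= min_umi) & annotated
    n_depth = int((umi < min_umi).sum())
    n_unannot = int((~annotated).sum())

    arrays = ds.obs["array_id"].to_numpy()
    row = ds.obs["row"].to_numpy()
    col = ds.obs["col"].to_numpy()
    n_isolated = 0
    changed = True
    while changed:
        changed = False
        for arr in np.unique(arrays):
            idx = np.flatnonzero((arrays == arr) & keep)
            if len(idx) == 0:
                continue
            edges = edges_from_coords(row[idx], col[idx])
            degree = np.zeros(len(idx), dtype=int)
            if len(edges):
                np.add.at(degree, edges[:, 0], 1)
                np.add.at(degree, edges[:, 1], 1)
            isolated = idx[degree == 0]
            if len(isolated):
                keep[isolated] = False
                n_isolated += len(isolated)
                changed = True
    if not keep.any():
        raise ValueError("all spots removed by depth/annotation/neighbor filters")
    logger.info(
        "filter_spots: %d below %d UMIs, %d unannotated, %d isolated, %d kept",
        n_depth,
        min_umi,
        n_unannot,
        n_isolated,
        int(keep.sum()),
    )
    return ds[keep].copy()


def qc_nuclei(ds: AnnData, min_umi: int = 500, max_mt: float = 0.05) -> AnnData:
    """Keep nuclei with nUMI > min_umi and MT fraction < max_mt, drop MT genes."""
    n_umi = np.asarray(ds.obs["n_umi"], dtype=float)
    mt_frac = np.asarray(ds.obs["mt_frac"], dtype=float)
    keep = (n_umi > min_umi) & (mt_frac < max_mt)
    if not keep.any():
        raise ValueError(
            f"no nuclei survive: {int((n_umi <= min_umi).sum())} at nUMI <= {min_umi}, "
            f"{int((mt_frac >= max_mt).sum())} at MT fraction >= {max_mt}"
        )
    out = ds[keep, ~ds.var["mitochondrial"].to_numpy()].copy()
    out.obs["n_umi"] = counts_matrix(out).sum(axis=1)
    out.obs["mt_frac"] = 0.0
    logger.info("qc_nuclei: kept %d of %d nuclei", int(keep.sum()), ds.n_obs)
    return out
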