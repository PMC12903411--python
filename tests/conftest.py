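import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from senespat.datasets import make_var
from senespat.simulate import SimConfig, generate_hallmark_genesets, generate_nuclei_dataset


@pytest.fixture(scope="session")
def nuclei_cfg():
    return SimConfig(seed=7, n_donors_per_group=5)


@pytest.fixture(scope="session")
def nuclei5(nuclei_cfg):
    """Default-condition nuclei dataset with planted senescent oligodendrocytes."""
    return generate_nuclei_dataset(nuclei_cfg)


@pytest.fixture(scope="session")
def hallmarks5(nuclei_cfg):
    return generate_hallmark_genesets(nuclei_cfg)


@pytest.fixture(scope="session")
def hallmark_scores(nuclei5, hallmarks5):
    from senespat.senescence import score_all_hallmarks

    nuc, _ = nuclei5
    return score_all_hallmarks(nuc, hallmarks5, seed=1)


def make_spatial(counts, row, col, aar, array_id=None, age_group="young", sex="M",
                 donor_id=None, var=None):
    """Assemble a spatial AnnData from arrays (test helper)."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "array_id": array_id if array_id is not None else ["a1"] * n,
            "donor_id": donor_id if donor_id is not None else ["d1"] * n,
            "age_group": age_group if not np.isscalar(age_group) else [age_group] * n,
            "sex": [sex] * n if np.isscalar(sex) else sex,
            "row": np.asarray(row),
            "col": np.asarray(col),
            "aar": aar if not np.isscalar(aar) else [aar] * n,
        },
        index=pd.Index([f"s{i}" for i in range(n)]),
    )
    if var is None:
        var = make_var([f"g{j}" for j in range(g)])
    return AnnData(X=counts.astype(np.int32), obs=obs, var=var)


def make_nuclei(counts, donor_id, age_group, age=None, batch=None, sex=None,
                broad_class=None, var=None, mito_mask=None):
    """Assemble a nuclei AnnData from arrays (test helper)."""
    counts = np.asarray(counts)
    n, g = counts.shape
    if var is None:
        var = make_var([f"g{j}" for j in range(g)], mitochondrial=mito_mask)
    mt_cols = var["mitochondrial"].to_numpy()
    n_umi = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mt_frac = np.where(n_umi > 0, counts[:, mt_cols].sum(axis=1) / n_umi, 0.0)
    obs = pd.DataFrame(
        {
            "donor_id": donor_id,
            "batch": batch if batch is not None else ["b1"] * n,
            "age": age if age is not None else [40.0] * n,
            "age_group": age_group,
            "sex": sex if sex is not None else ["M"] * n,
            "broad_class": broad_class if broad_class is not None else ["Oli"] * n,
            "subcluster": ["x"] * n,
            "n_umi": n_umi,
            "mt_frac": mt_frac,
        },
        index=pd.Index([f"n{i}" for i in range(n)]),
    )
    return AnnData(X=counts.astype(np.int32), obs=obs, var=var)
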