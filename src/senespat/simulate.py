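"""Synthetic spatial and single-nucleus datasets with planted ground truth.

The spatial generator emits zero-inflated Poisson (ZIP) counts on square
arrays of spots laid out as horizontal cortical bands (L1..L6, WM): for
spot ``s`` and gene ``g``,

    y_sg ~ ZIP(lambda_sg, theta),
    log lambda_sg = beta[g, aar(s), group(donor(s))] + psi_sg + eps_sg,

where ``beta`` is the characteristic log counts/spot of the gene in an
anatomical region for a donor group, ``psi`` is a spatially autocorrelated
effect drawn from a proper conditional-autoregressive (CAR) model on the
rook-adjacency grid and rescaled to ``spatial_sd``, and ``eps`` is i.i.d.
spot noise. ``theta`` is the structural-dropout probability.

The nuclei generator emits Poisson counts from cell-type-specific
expression programs (shared baseline, elevated markers), with planted
senescent subpopulations that over-express designated hallmark gene sets.

Defaults describe a desk-scale study: three age groups (young <45,
middle 45-55, old >55 years), a MEDIUM characteristic rate of 0.6
counts/spot, theta = 0.1, 15 x 15 arrays, and senescent oligodendrocyte
fractions rising with age. All outputs are byte-deterministic given the
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from ._grid import grid_edges, laplacian
from .datasets import AARS, AGE_GROUPS, BROAD_CLASSES, make_var
from .genesets import HallmarkGeneSets, INDIVIDUAL_HALLMARKS, MULTI_HALLMARKS

#: Default cell-type mixture of cortical tissue (fractions sum to 1).
DEFAULT_CLASS_PROPORTIONS = {
    "Exc": 0.35,
    "Oli": 0.20,
    "Ast": 0.12,
    "Inh": 0.12,
    "Mic": 0.06,
    "OPC": 0.06,
    "End": 0.05,
    "Peri": 0.04,
}

#: Age-group midpoints in years, used when exact ages are unavailable.
AGE_GROUP_MIDPOINTS = {"young": 35.0, "middle": 50.0, "old": 70.0}

_AGE_RANGES = {"young": (28, 44), "middle": (45, 55), "old": (56, 78)}


@dataclass
class PlantedModule:
    """A planted coexpression module: genes sharing an AAR/age profile."""

    genes: list[int]
    aar_log_effect: dict[str, float] = field(default_factory=dict)
    group_log_effect: dict[str, float] = field(default_factory=dict)


@dataclass
class PlantedSenescence:
    """Planted senescent subpopulation of one broad class.

    ``fraction_by_group`` gives the senescent fraction per age group;
    senescent nuclei have the member genes of each listed hallmark
    multiplied by ``effect_size`` in their expression program, and CDKN2A
    (p16, in the cell-cycle-arrest list) multiplied by ``cdkn2a_effect``:
    p16 induction defines senescent cells, so the default makes most
    planted senescent nuclei transcript-positive while baseline nuclei
    detect CDKN2A in only a few percent.
    """

    cell_type: str = "Oli"
    fraction_by_group: dict[str, float] = field(
        default_factory=lambda: {"young": 0.02, "middle": 0.06, "old": 0.12}
    )
    effect_size: float = 2.0
    cdkn2a_effect: float = 25.0
    hallmarks: tuple[str, ...] = INDIVIDUAL_HALLMARKS


@dataclass
class SimConfig:
    """Study design and generative parameters for the synthetic datasets."""

    n_donors_per_group: int = 4
    arrays_per_donor: int = 1
    grid_shape: tuple[int, int] = (15, 15)
    n_genes: int = 2500
    #: rows per AAR band (L1..L6, WM), must sum to grid rows
    aar_layout: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 3)
    theta: float = 0.1
    #: gene x AAR x group natural-log counts/spot; default ln(0.6) (MEDIUM)
    beta_table: np.ndarray | None = None
    base_rate: float = 0.6
    spatial_sd: float = 0.0
    noise_sd: float = 0.0
    planted_modules: list[PlantedModule] = field(default_factory=list)
    planted_senescence: PlantedSenescence | None = field(
        default_factory=PlantedSenescence
    )
    # nuclei design
    n_nuclei_per_donor: int = 300
    depth: float = 4000.0
    n_batches: int = 4
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    donor_proportion_sd: float = 0.2
    markers_per_type: int = 20
    marker_strength: float = 8.0
    # hallmark gene lists
    hallmark_size: int = 40
    hallmark_overlap: bool = True
    control_pool_size: int = 2000
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if len(self.aar_layout) != len(AARS):
            raise ValueError("aar_layout must give a band width per AAR")
        if sum(self.aar_layout) != rows:
            raise ValueError(
                f"aar_layout bands sum to {sum(self.aar_layout)}, grid has {rows} rows"
            )
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.spatial_sd < 0 or self.noise_sd < 0:
            raise ValueError("effect scales must be non-negative")
        if self.n_genes < 1 or rows * cols < 2:
            raise ValueError("need at least 1 gene and 2 spots")
        if self.beta_table is not None:
            b = np.asarray(self.beta_table)
            if b.shape != (self.n_genes, len(AARS), len(AGE_GROUPS)):
                raise ValueError(
                    f"beta_table shape {b.shape} != "
                    f"({self.n_genes}, {len(AARS)}, {len(AGE_GROUPS)})"
                )
            if not np.all(np.isfinite(b)):
                raise ValueError("beta_table must be finite")
        if self.planted_senescence is not None:
            for f in self.planted_senescence.fraction_by_group.values():
                if not 0.0 <= f <= 1.0:
                    raise ValueError("senescent fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each synthetic dataset."""

    true_beta: np.ndarray | None = None
    true_module_of_gene: dict[str, int] = field(default_factory=dict)
    true_senescent: np.ndarray | None = None
    true_markers: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "true_beta": None if self.true_beta is None else self.true_beta.tolist(),
            "true_module_of_gene": self.true_module_of_gene,
            "true_senescent": None
            if self.true_senescent is None
            else self.true_senescent.astype(int).tolist(),
            "true_markers": self.true_markers,
        }
        Path(path).write_text(json.dumps(obj))


def resolved_beta_table(cfg: SimConfig) -> np.ndarray:
    """The gene x AAR x group log-rate table with planted module effects."""
    if cfg.beta_table is not None:
        beta = np.array(cfg.beta_table, dtype=float)
    else:
        beta = np.full(
            (cfg.n_genes, len(AARS), len(AGE_GROUPS)), np.log(cfg.base_rate)
        )
    for mod in cfg.planted_modules:
        for a, aar in enumerate(AARS):
            eff = mod.aar_log_effect.get(aar, 0.0)
            beta[np.ix_(mod.genes, [a])] += eff
        for g, grp in enumerate(AGE_GROUPS):
            eff = mod.group_log_effect.get(grp, 0.0)
            beta[np.ix_(mod.genes, range(len(AARS)), [g])] += eff
    return beta


def donor_table(cfg: SimConfig) -> pd.DataFrame:
    """Donor roster: id, age group, sex (alternating within group), batch, age."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    rows = []
    for grp in AGE_GROUPS:
        lo, hi = _AGE_RANGES[grp]
        ages = np.sort(rng.integers(lo, hi + 1, size=cfg.n_donors_per_group))
        for i in range(cfg.n_donors_per_group):
            rows.append(
                {
                    "donor_id": f"{grp[0].upper()}{i + 1}",
                    "age_group": grp,
                    "sex": "M" if i % 2 == 0 else "F",
                    "age": float(ages[i]),
                }
            )
    df = pd.DataFrame(rows)
    df["batch"] = [f"B{i % cfg.n_batches + 1}" for i in range(len(df))]
    return df


def build_gene_table(n_genes: int, n_mito: int = 5, n_lnc: int = 5, n_pseudo: int = 5):
    """Gene metadata: CDKN2A first, then flagged biotypes, then G####."""
    if n_genes < 1 + n_mito + n_lnc + n_pseudo:
        n_mito = n_lnc = n_pseudo = 0
    symbols, mito, lnc, pseudo = [], [], [], []
    for i in range(n_genes):
        if i == 0:
            symbols.append("CDKN2A")
            m = l = p = False
        elif i <= n_mito:
            symbols.append(f"MT-G{i:03d}")
            m, l, p = True, False, False
        elif i <= n_mito + n_lnc:
            symbols.append(f"LINC{i:04d}")
            m, l, p = False, True, False
        elif i <= n_mito + n_lnc + n_pseudo:
            symbols.append(f"G{i:04d}P")
            m, l, p = False, False, True
        else:
            symbols.append(f"G{i:04d}")
            m = l = p = False
        mito.append(m)
        lnc.append(l)
        pseudo.append(p)
    return make_var(symbols, mito, lnc, pseudo)


def _car_factor(rows: int, cols: int) -> np.ndarray:
    """Cholesky factor of the proper-CAR precision on the grid."""
    n = rows * cols
    Q = laplacian(n, grid_edges(rows, cols)) + 0.1 * np.eye(n)
    return np.linalg.cholesky(Q)


def _car_draws(chol: np.ndarray, n_draws: int, sd: float, rng) -> np.ndarray:
    """Draw n_draws CAR fields scaled to marginal sd; shape (n_spots, n_draws)."""
    z = rng.standard_normal((chol.shape[0], n_draws))
    x = np.linalg.solve(chol.T, z)
    x -= x.mean(axis=0)
    s = x.std(axis=0)
    s[s == 0] = 1.0
    return sd * x / s


def generate_spatial_dataset(cfg: SimConfig):
    """ZIP spatial counts with planted truth.

    Returns an AnnData (spots x genes) following the spatial schema and a
    :class:`GroundTruth` carrying the effective beta table and planted
    module memberships.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    beta = resolved_beta_table(cfg)
    donors = donor_table(cfg)
    rows, cols = cfg.grid_shape
    n_spots_arr = rows * cols
    aar_of_row = np.repeat(np.arange(len(AARS)), cfg.aar_layout)
    spot_row, spot_col = np.divmod(np.arange(n_spots_arr), cols)
    aar_idx = aar_of_row[spot_row]

    chol = _car_factor(rows, cols) if cfg.spatial_sd > 0 else None
    group_index = {g: i for i, g in enumerate(AGE_GROUPS)}

    blocks, obs_frames = [], []
    for _, donor in donors.iterrows():
        gi = group_index[donor["age_group"]]
        for a in range(cfg.arrays_per_donor):
            array_id = f"{donor['donor_id']}_a{a + 1}"
            log_lam = beta[:, aar_idx, gi].T  # (spots, genes)
            if cfg.spatial_sd > 0:
                log_lam = log_lam + _car_draws(chol, cfg.n_genes, cfg.spatial_sd, rng)
            if cfg.noise_sd > 0:
                log_lam = log_lam + rng.normal(
                    0.0, cfg.noise_sd, size=(n_spots_arr, cfg.n_genes)
                )
            counts = rng.poisson(np.exp(log_lam))
            if cfg.theta > 0:
                counts[rng.random(size=counts.shape) < cfg.theta] = 0
            blocks.append(sparse.csr_matrix(counts.astype(np.int32)))
            obs_frames.append(
                pd.DataFrame(
                    {
                        "array_id": array_id,
                        "donor_id": donor["donor_id"],
                        "age_group": donor["age_group"],
                        "sex": donor["sex"],
                        "row": spot_row,
                        "col": spot_col,
                        "aar": np.asarray(AARS)[aar_idx],
                    }
                )
            )
    obs = pd.concat(obs_frames, ignore_index=True)
    obs.index = pd.Index([f"spot{i}" for i in range(len(obs))], name="spot")
    var = build_gene_table(cfg.n_genes)
    adata = AnnData(X=sparse.vstack(blocks).tocsr(), obs=obs, var=var)

    module_of_gene = {}
    for m, mod in enumerate(cfg.planted_modules):
        for g in mod.genes:
            module_of_gene[var.index[g]] = m
    truth = GroundTruth(true_beta=beta, true_module_of_gene=module_of_gene)
    return adata, truth


def generate_hallmark_genesets(cfg: SimConfig) -> HallmarkGeneSets:
    """Carve 3 multi-hallmark and 7 individual hallmark lists from the genes.

    Lists are taken from unflagged genes; CDKN2A is placed in the
    cell-cycle-arrest list. With ``hallmark_overlap`` the multi-hallmark
    lists mix fresh genes with genes re-sampled from the individual lists
    (as curated multi-hallmark panels do). The complement of all lists is
    the control pool, from which a fixed control set of
    ``control_pool_size`` genes is sampled.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    var = build_gene_table(cfg.n_genes)
    eligible = var.index[
        ~(var["mitochondrial"] | var["lncRNA"] | var["pseudogene"])
    ].tolist()
    eligible = [g for g in eligible if g != "CDKN2A"]

    need = cfg.hallmark_size * (len(INDIVIDUAL_HALLMARKS) + len(MULTI_HALLMARKS))
    if len(eligible) < need:
        raise ValueError(
            f"{len(eligible)} eligible genes cannot host {need} hallmark slots"
        )
    chosen = list(rng.choice(eligible, size=need, replace=False))
    individual: dict[str, list[str]] = {}
    pos = 0
    for name in INDIVIDUAL_HALLMARKS:
        genes = chosen[pos : pos + cfg.hallmark_size]
        pos += cfg.hallmark_size
        if name == "cell_cycle_arrest":
            genes = ["CDKN2A"] + genes[:-1]
        individual[name] = genes
    ind_union = sorted({g for genes in individual.values() for g in genes})
    multi: dict[str, list[str]] = {}
    for name in MULTI_HALLMARKS:
        fresh = chosen[pos : pos + cfg.hallmark_size]
        pos += cfg.hallmark_size
        if cfg.hallmark_overlap:
            half = cfg.hallmark_size // 2
            borrowed = list(rng.choice(ind_union, size=half, replace=False))
            multi[name] = fresh[: cfg.hallmark_size - half] + borrowed
        else:
            multi[name] = fresh

    members = {g for genes in individual.values() for g in genes}
    members |= {g for genes in multi.values() for g in genes}
    pool = [g for g in var.index if g not in members]
    if len(pool) < cfg.control_pool_size:
        raise ValueError(
            f"only {len(pool)} non-member genes for a "
            f"{cfg.control_pool_size}-gene control pool"
        )
    control_set = sorted(rng.choice(pool, size=cfg.control_pool_size, replace=False))
    hgs = HallmarkGeneSets(
        multi=multi, individual=individual, control_pool=pool, control_set=control_set
    )
    hgs.validate()
    return hgs


def generate_nuclei_dataset(cfg: SimConfig):
    """Poisson single-nucleus counts from cell-type programs.

    Each broad class shares a lognormal baseline program with its own
    elevated marker genes; planted senescent nuclei multiply the member
    genes of the designated hallmark lists by the configured effect size.
    Returns an AnnData following the nuclei schema and a
    :class:`GroundTruth` with the per-nucleus senescent flag and the true
    marker sets.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    var = build_gene_table(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(var.index)}
    classes = list(cfg.class_proportions)
    unknown = set(classes) - set(BROAD_CLASSES)
    if unknown:
        raise ValueError(f"unknown broad classes: {sorted(unknown)}")

    baseline = rng.lognormal(mean=np.log(0.1), sigma=1.0, size=cfg.n_genes)
    # CDKN2A (p16) is a low-expressed transcript: pin its baseline so only
    # a few percent of nuclei detect it at the default depth
    baseline[gene_index["CDKN2A"]] = 0.005
    mt_mask = var["mitochondrial"].to_numpy()
    if mt_mask.any():
        # pin mitochondrial content near 2% of reads
        baseline[mt_mask] = 0.02 * baseline[~mt_mask].sum() / (0.98 * mt_mask.sum())

    # disjoint marker sets per class, drawn from unflagged non-hallmark genes
    hallmark_members: set[str] = set()
    sen = cfg.planted_senescence
    hgs = None
    if sen is not None:
        hgs = generate_hallmark_genesets(cfg)
        hallmark_members = hgs.members()
    eligible = [
        g
        for g in var.index
        if g not in hallmark_members
        and g != "CDKN2A"
        and not (
            var.at[g, "mitochondrial"] or var.at[g, "lncRNA"] or var.at[g, "pseudogene"]
        )
    ]
    need = cfg.markers_per_type * len(classes)
    if len(eligible) < need:
        raise ValueError(f"{len(eligible)} eligible genes < {need} marker slots")
    marker_pick = list(rng.choice(eligible, size=need, replace=False))
    true_markers = {
        t: marker_pick[i * cfg.markers_per_type : (i + 1) * cfg.markers_per_type]
        for i, t in enumerate(classes)
    }

    programs = {}
    for t in classes:
        prog = baseline.copy()
        prog[[gene_index[g] for g in true_markers[t]]] *= cfg.marker_strength
        programs[t] = prog

    sen_multiplier = np.ones(cfg.n_genes)
    if sen is not None:
        genes = set()
        for h in sen.hallmarks:
            genes.update(hgs.all_lists[h])
        sen_multiplier[[gene_index[g] for g in sorted(genes)]] = sen.effect_size
        sen_multiplier[gene_index["CDKN2A"]] = sen.cdkn2a_effect

    donors = donor_table(cfg)
    props = np.array([cfg.class_proportions[t] for t in classes])
    X_rows, obs_rows, sen_flags = [], [], []
    for _, donor in donors.iterrows():
        logit = np.log(props) + rng.normal(0, cfg.donor_proportion_sd, len(props))
        p = np.exp(logit) / np.exp(logit).sum()
        type_idx = rng.choice(len(classes), size=cfg.n_nuclei_per_donor, p=p)
        depths = rng.lognormal(np.log(cfg.depth), 0.25, size=cfg.n_nuclei_per_donor)
        sen_frac = (
            sen.fraction_by_group.get(donor["age_group"], 0.0) if sen else 0.0
        )
        for i in range(cfg.n_nuclei_per_donor):
            t = classes[type_idx[i]]
            prog = programs[t]
            is_sen = bool(
                sen is not None and t == sen.cell_type and rng.random() < sen_frac
            )
            if is_sen:
                prog = prog * sen_multiplier
            rate = depths[i] * prog / prog.sum()
            counts = rng.poisson(rate)
            X_rows.append(counts.astype(np.int32))
            sen_flags.append(is_sen)
            obs_rows.append(
                {
                    "donor_id": donor["donor_id"],
                    "batch": donor["batch"],
                    "age": donor["age"],
                    "age_group": donor["age_group"],
                    "sex": donor["sex"],
                    "broad_class": t,
                    "subcluster": f"{t}_s0",
                }
            )
    X = np.vstack(X_rows)
    obs = pd.DataFrame(obs_rows)
    obs.index = pd.Index([f"nuc{i}" for i in range(len(obs))], name="nucleus")
    obs["n_umi"] = X.sum(axis=1)
    mt_sum = X[:, mt_mask].sum(axis=1) if mt_mask.any() else np.zeros(len(obs))
    with np.errstate(invalid="ignore"):
        obs["mt_frac"] = np.where(obs["n_umi"] > 0, mt_sum / obs["n_umi"], 0.0)
    adata = AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
    truth = GroundTruth(
        true_senescent=np.asarray(sen_flags, dtype=bool), true_markers=true_markers
    )
    return adata, truth
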