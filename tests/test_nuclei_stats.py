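"""MASC mixed-effects composition tests, pseudobulk DE, ROC marker ranking."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_nuclei
from senespat.nuclei_stats import auc_rank_markers, masc_test, pseudobulk_de


def _sim_masc(rng, or_=1.0, n_donors=10, n_per=100, sd_donor=0.3, base_logit=-2.0):
    """Binomial cluster membership with donor random intercepts."""
    rows, member = [], []
    for g, grp in ((0, "young"), (1, "old")):
        for d in range(n_donors):
            u = rng.normal(0, sd_donor)
            p = 1.0 / (1.0 + np.exp(-(base_logit + np.log(or_) * g + u)))
            member.append(rng.random(n_per) < p)
            rows.append(
                pd.DataFrame(
                    {
                        "donor_id": f"{grp}{d}",
                        "batch": f"B{d % 4}",
                        "sex": "M" if d % 2 else "F",
                        "age_group": grp,
                    },
                    index=range(n_per),
                )
            )
    obs = pd.concat(rows, ignore_index=True)
    obs.index = obs.index.astype(str)
    ad = AnnData(X=np.zeros((len(obs), 1)), obs=obs)
    return ad, np.concatenate(member)


class TestMasc:
    def test_no_covariate_toy_matches_contingency_or(self):
        """Without random effects the OR equals the closed-form 2x2 table OR."""
        obs = pd.DataFrame(
            {
                "donor_id": ["d1"] * 200 + ["d2"] * 200,
                "batch": "b1",
                "sex": "M",
                "age_group": ["young"] * 200 + ["old"] * 200,
            },
            index=[str(i) for i in range(400)],
        )
        member = np.r_[
            np.ones(40, bool), np.zeros(160, bool),
            np.ones(80, bool), np.zeros(120, bool),
        ]
        ad = AnnData(X=np.zeros((400, 1)), obs=obs)
        res = masc_test(ad, member, ("old", "young"), random_effects=(),
                        include_sex=False)
        closed = (80 * 160) / (120 * 40)
        assert res.odds_ratio == pytest.approx(closed, rel=1e-3)

    def test_balanced_identical_membership_gives_or_one(self):
        """Every donor has exactly 12/100 member nuclei: OR ~ 1 exactly."""
        rng = np.random.default_rng(0)
        ad, _ = _sim_masc(rng, or_=1.0, sd_donor=0.0)
        member = np.tile(np.r_[np.ones(12, bool), np.zeros(88, bool)], 20)
        res = masc_test(ad, member)
        assert 0.9 < res.odds_ratio < 1.1

    def test_null_lrt_p_uniform(self):
        """LRT p-values under the null pass a KS test against U(0,1)."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            ad, member = _sim_masc(rng)
            ps.append(masc_test(ad, member).p)
        assert stats.kstest(np.asarray(ps), "uniform").pvalue > 0.01

    def test_or_two_recovered_with_ci_coverage(self):
        """True OR 2.0 with donor effects: 95% CI covers it in >= 90/100 reps."""
        rng = np.random.default_rng(7)
        covered = 0
        for _ in range(100):
            ad, member = _sim_masc(rng, or_=2.0)
            res = masc_test(ad, member)
            covered += res.ci_low <= 2.0 <= res.ci_high
        assert covered >= 90

    def test_separation_reported_not_raised(self):
        rng = np.random.default_rng(1)
        ad, member = _sim_masc(rng, or_=1.0)
        member[(ad.obs.age_group == "young").to_numpy()] = False
        res = masc_test(ad, member)
        assert res.separated and res.odds_ratio == np.inf

    def test_agrees_with_lme4_glmer(self):
        """Cross-check the GLMM against R/lme4 on one fixture (log-OR)."""
        rng = np.random.default_rng(3)
        rows, member = [], []
        for g, grp in ((0, "young"), (1, "old")):
            for d in range(8):
                u = rng.normal(0, 0.4)
                p = 1 / (1 + np.exp(-(-1.5 + 0.6 * g + u)))
                member.append(rng.random(150) < p)
                rows.append(pd.DataFrame(
                    {"donor_id": f"{grp}{d}", "batch": f"B{d % 3}",
                     "sex": "M" if d % 2 else "F", "age_group": grp},
                    index=range(150)))
        obs = pd.concat(rows, ignore_index=True)
        obs.index = obs.index.astype(str)
        ad = AnnData(X=np.zeros((len(obs), 1)), obs=obs)
        mem = np.concatenate(member)
        res = masc_test(ad, mem)

        units = (
            obs.assign(member=mem)
            .groupby(["donor_id", "batch", "sex", "age_group"], observed=True)
            ["member"].agg(["sum", "count"]).reset_index()
        )
        units["is_a"] = (units.age_group == "old").astype(int)
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as td:
            tsv = pathlib.Path(td) / "units.tsv"
            units.rename(columns={"sum": "y", "count": "n",
                                  "donor_id": "donor"}).to_csv(
                tsv, sep="\t", index=False)
            rcode = (
                "suppressMessages(library(lme4));"
                f"d <- read.table('{tsv}', header=TRUE, sep='\\t');"
                "m <- glmer(cbind(y, n - y) ~ is_a + sex + (1|donor) + (1|batch),"
                " data=d, family=binomial);"
                "cat(fixef(m)['is_a'])"
            )
            out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                                 text=True, timeout=300)
            lme4_logor = float(out.stdout.strip().split()[-1])
        assert np.log(res.odds_ratio) == pytest.approx(lme4_logor, abs=0.05)


def _sim_pseudobulk_nuclei(rng, n_donors=12, n_nuclei=20, n_genes=150,
                           planted_lfc=0.0, permute_ages=False):
    """Poisson nuclei for 12 young + 12 old donors; gene 0 optionally planted.

    ``planted_lfc`` is the log2 fold change over the 35-year young-to-old
    midpoint span (rate scales as 2^(lfc * (age - 35) / 35)).
    """
    X_rows, donor_id, age_group, age_col, sex, batch = [], [], [], [], [], []
    ages = np.r_[rng.integers(28, 45, n_donors), rng.integers(56, 79, n_donors)]
    if permute_ages:
        ages = rng.permutation(ages)
    for d in range(2 * n_donors):
        rate = np.full(n_genes, 2.0)
        rate[0] *= 2.0 ** (planted_lfc * (ages[d] - 35.0) / 35.0)
        X_rows.append(rng.poisson(rate, size=(n_nuclei, n_genes)))
        donor_id += [f"d{d}"] * n_nuclei
        age_group += ["young" if d < n_donors else "old"] * n_nuclei
        age_col += [float(ages[d])] * n_nuclei
        sex += ["M" if d % 2 else "F"] * n_nuclei
        batch += [f"B{d % 3}"] * n_nuclei
    return make_nuclei(np.vstack(X_rows), donor_id, age_group, age=age_col,
                       batch=batch, sex=sex)


class TestPseudobulkDe:
    def test_min_nuclei_filter(self):
        """A gene expressed in only 25 nuclei is dropped by the 30-nucleus rule."""
        rng = np.random.default_rng(0)
        nuc = _sim_pseudobulk_nuclei(rng, n_donors=3, n_nuclei=30, n_genes=10)
        X = nuc.X.copy()
        X[:, 5] = 0
        rows = rng.choice(X.shape[0], size=25, replace=False)
        X[rows, 5] = 1
        nuc.X = X
        nuc.obs["n_umi"] = X.sum(axis=1)
        table = pseudobulk_de(nuc, "Oli")
        assert "g5" not in set(table.gene)

    def test_planted_age_effect_detected_with_correct_sign(self):
        """2-fold old/young gene: q < 0.05 and positive sign in >=90% of 50 sims."""
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(50):
            nuc = _sim_pseudobulk_nuclei(rng, planted_lfc=1.0)
            table = pseudobulk_de(nuc, "Oli")
            row = table[table.gene == "g0"].iloc[0]
            wins += int(row.q < 0.05 and row.log2fc > 0)
        assert wins >= 45

    def test_null_fdr_controlled(self):
        """With permuted ages, ~<=5% of genes reach q < 0.05."""
        rng = np.random.default_rng(2)
        rates = []
        for _ in range(20):
            nuc = _sim_pseudobulk_nuclei(rng, permute_ages=True)
            table = pseudobulk_de(nuc, "Oli")
            rates.append((table.q < 0.05).mean())
        assert np.mean(rates) <= 0.05

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(3)
        nuc = _sim_pseudobulk_nuclei(rng, n_donors=4)
        # batch perfectly confounded with age group
        nuc.obs["batch"] = np.where(nuc.obs.age_group == "young", "B1", "B2")
        nuc.obs["age"] = np.where(nuc.obs.age_group == "young", 30.0, 70.0)
        with pytest.raises(ValueError, match="confounded.*batch"):
            pseudobulk_de(nuc, "Oli")


class TestAucMarkers:
    def test_worked_example_with_tie(self):
        """Group A (3,4,5) vs B (1,2,3): AUC = 8.5/9."""
        X = np.array([[3], [4], [5], [1], [2], [3]])
        nuc = make_nuclei(X, ["d"] * 6, ["young"] * 6)
        a = np.array([1, 1, 1, 0, 0, 0], bool)
        table = auc_rank_markers(nuc, a, ~a)
        assert table.auc.iloc[0] == pytest.approx(8.5 / 9)

    def test_disjoint_and_identical_distributions(self):
        rng = np.random.default_rng(0)
        X = np.zeros((40, 2))
        X[:20, 0] = rng.integers(1, 5, 20)          # expressed only in A
        X[:, 1] = np.tile(rng.integers(0, 5, 20), 2)  # identical in A and B
        nuc = make_nuclei(X, ["d"] * 40, ["young"] * 40)
        a = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        table = auc_rank_markers(nuc, a, ~a).set_index("gene")
        assert table.loc["g0", "auc"] == pytest.approx(1.0)
        assert table.loc["g1", "auc"] == pytest.approx(0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.poisson(3.0, size=(30, 4)).astype(float)
        nuc1 = make_nuclei(X, ["d"] * 30, ["young"] * 30)
        nuc2 = make_nuclei(np.expm1(np.sqrt(X)), ["d"] * 30, ["young"] * 30)
        a = np.zeros(30, bool)
        a[rng.choice(30, 12, replace=False)] = True
        t1 = auc_rank_markers(nuc1, a, ~a).set_index("gene").auc
        t2 = auc_rank_markers(nuc2, a, ~a).set_index("gene").auc
        pd.testing.assert_series_equal(t1, t2)

    def test_empty_group_rejected(self):
        nuc = make_nuclei(np.ones((4, 1)), ["d"] * 4, ["young"] * 4)
        with pytest.raises(ValueError, match="non-empty"):
            auc_rank_markers(nuc, np.zeros(4, bool), np.ones(4, bool))
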