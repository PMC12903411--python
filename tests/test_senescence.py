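"""Hallmark module scores, young-referenced positivity, CDKN2A analyses."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_nuclei
from senespat.coexpression import normalize_log1p
from senespat.datasets import counts_matrix
from senespat.genesets import INDIVIDUAL_HALLMARKS
from senespat.senescence import (
    classify_positive,
    cdkn2a_positivity,
    nuclei_module_score,
    positivity_thresholds,
    proportion_difference_stat,
)
from senespat.senescence import test_positivity_by_age as positivity_by_age
from senespat.simulate import (
    PlantedSenescence,
    SimConfig,
    generate_hallmark_genesets,
    generate_nuclei_dataset,
)


class TestModuleScore:
    def test_two_gene_arithmetic(self):
        """One set gene, one control gene: score is their normalized difference."""
        X = np.array([[30, 10], [5, 15]])
        nuc = make_nuclei(X, ["d"] * 2, ["young"] * 2)
        score = nuclei_module_score(nuc, ["g0"], ["g1"], n_bins=1)
        norm = normalize_log1p(X.astype(float))
        np.testing.assert_allclose(score, norm[:, 0] - norm[:, 1])

    def test_identical_distributions_score_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3.0, size=(300, 400))
        nuc = make_nuclei(X, ["d"] * 300, ["young"] * 300)
        score = nuclei_module_score(
            nuc, [f"g{j}" for j in range(40)],
            [f"g{j}" for j in range(40, 400)], seed=1,
        )
        assert abs(score.mean()) < 0.02

    def test_planted_senescent_nuclei_score_higher(self, nuclei5, hallmarks5,
                                                   hallmark_scores):
        nuc, truth = nuclei5
        sen = truth.true_senescent
        for hallmark in INDIVIDUAL_HALLMARKS:
            gap = (hallmark_scores.loc[sen, hallmark].mean()
                   - hallmark_scores.loc[~sen, hallmark].mean())
            assert gap > 0.1

    def test_constant_expression_shift_cancels(self):
        """Adding a constant to all normalized expression leaves scores unchanged."""
        rng = np.random.default_rng(2)
        X = rng.poisson(2.0, size=(100, 200))
        nuc = make_nuclei(X, ["d"] * 100, ["young"] * 100)
        norm = normalize_log1p(X.astype(float))
        sets = [f"g{j}" for j in range(20)]
        ctrl = [f"g{j}" for j in range(20, 200)]
        s0 = nuclei_module_score(nuc, sets, ctrl, seed=3, normalized=norm)
        s1 = nuclei_module_score(nuc, sets, ctrl, seed=3, normalized=norm + 1.7)
        np.testing.assert_allclose(s0, s1, atol=1e-12)

    def test_overlap_with_control_rejected(self):
        nuc = make_nuclei(np.ones((5, 3)), ["d"] * 5, ["young"] * 5)
        with pytest.raises(ValueError, match="overlap"):
            nuclei_module_score(nuc, ["g0"], ["g0", "g1"])


class TestThresholds:
    def test_scores_1_to_100_give_95_05(self):
        scores = pd.DataFrame({"h": np.arange(1.0, 101.0)})
        young = np.ones(100, bool)
        cls = np.array(["Oli"] * 100)
        thr = positivity_thresholds(scores, young, cls)
        assert thr.threshold.iloc[0] == pytest.approx(95.05)
        assert (scores["h"] > 95.05).sum() == 5

    def test_constant_scores_yield_zero_positives(self):
        scores = pd.DataFrame({"h": np.full(50, 2.5)})
        thr = positivity_thresholds(scores, np.ones(50, bool), ["Oli"] * 50)
        assert thr.threshold.iloc[0] == 2.5
        pos = classify_positive(scores, thr, ["Oli"] * 50)
        assert pos["h"].sum() == 0  # strict >

    def test_normal_quantile_large_sample(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame({"h": rng.standard_normal(10_000)})
        thr = positivity_thresholds(scores, np.ones(10_000, bool), ["Oli"] * 10_000)
        assert thr.threshold.iloc[0] == pytest.approx(1.645, abs=0.05)

    def test_small_stratum_undefined(self):
        scores = pd.DataFrame({"h": np.arange(10.0)})
        thr = positivity_thresholds(scores, np.ones(10, bool), ["Oli"] * 10)
        assert np.isnan(thr.threshold.iloc[0])
        pos = classify_positive(scores, thr, ["Oli"] * 10)
        assert pos["h"].isna().all()


class TestClassify:
    def test_score_equal_threshold_is_negative(self):
        scores = pd.DataFrame({"h": [1.0, 2.0]})
        thr = pd.DataFrame([{"broad_class": "Oli", "hallmark": "h",
                             "threshold": 2.0}])
        pos = classify_positive(scores, thr, ["Oli", "Oli"])
        assert list(pos["h"]) == [False, False]

    def test_three_hallmark_flag(self):
        cols = list(INDIVIDUAL_HALLMARKS)
        scores = pd.DataFrame([[1.0] * 7, [1.0] * 3 + [-1.0] * 4], columns=cols)
        thr = pd.DataFrame([{"broad_class": "Oli", "hallmark": h, "threshold": 0.0}
                            for h in cols])
        pos = classify_positive(scores, thr, ["Oli", "Oli"])
        assert list(pos.multi_hallmark) == [True, True]
        scores.iloc[1, 2] = -1.0  # now only 2 positive hallmarks
        pos = classify_positive(scores, thr, ["Oli", "Oli"])
        assert list(pos.multi_hallmark) == [True, False]

    def test_young_positivity_near_five_percent(self, nuclei5, hallmark_scores):
        """By construction of the young-top-5% threshold."""
        nuc, _ = nuclei5
        young = (nuc.obs.age_group == "young").to_numpy()
        cls = nuc.obs.broad_class.to_numpy()
        thr = positivity_thresholds(hallmark_scores, young, cls)
        pos = classify_positive(hallmark_scores, thr, cls)
        rates = pos.loc[young, list(INDIVIDUAL_HALLMARKS)].astype("boolean").mean()
        assert (np.abs(rates.to_numpy(dtype=float) - 0.05) < 0.01).all()


class TestCdkn2a:
    def test_counts_to_positivity_fraction(self):
        X = np.array([[0], [1], [3], [0]])
        nuc = make_nuclei(X, ["d1"] * 4, ["young"] * 4)
        nuc.var_names = ["CDKN2A"]
        table, _ = cdkn2a_positivity(nuc, cell_class=None)
        assert table.pct_positive.iloc[0] == 50.0

    def test_linear_positivity_r2_one(self):
        rows_X, donors, ages = [], [], []
        for d, age in enumerate([30.0, 40.0, 50.0, 60.0]):
            frac = 0.1 + 0.01 * age  # exactly linear in age
            n = 100
            x = np.zeros((n, 1), int)
            x[: int(round(frac * n)), 0] = 2
            rows_X.append(x)
            donors += [f"d{d}"] * n
            ages += [age] * n
        nuc = make_nuclei(np.vstack(rows_X), donors, ["young"] * 400, age=ages)
        nuc.var_names = ["CDKN2A"]
        table, trend = cdkn2a_positivity(nuc, cell_class=None)
        assert trend["r2"] == pytest.approx(1.0)
        assert trend["slope"] == pytest.approx(1.0)  # % per year

    def test_slope_recovery_under_noise(self):
        """positivity = 0.05 + 0.002*age + N(0, 0.01): slope within 2 SE."""
        rng = np.random.default_rng(8)
        rows_X, donors, ages = [], [], []
        for d in range(30):
            age = float(rng.integers(25, 80))
            frac = np.clip(0.05 + 0.002 * age + rng.normal(0, 0.01), 0, 1)
            n = 400
            x = np.zeros((n, 1), int)
            x[: int(round(frac * n)), 0] = 1
            rows_X.append(x)
            donors += [f"d{d}"] * n
            ages += [age] * n
        nuc = make_nuclei(np.vstack(rows_X), donors, ["young"] * (30 * 400),
                          age=ages)
        nuc.var_names = ["CDKN2A"]
        _, trend = cdkn2a_positivity(nuc, cell_class=None)
        assert abs(trend["slope"] - 0.2) < 2 * trend["stderr"]  # % per year

    def test_donor_without_class_nuclei_excluded(self):
        X = np.array([[1], [0]])
        nuc = make_nuclei(X, ["d1", "d2"], ["young", "young"],
                          broad_class=["Oli", "Ast"])
        nuc.var_names = ["CDKN2A"]
        table, _ = cdkn2a_positivity(nuc, cell_class="Oli")
        assert list(table.donor_id) == ["d1"]


class TestPositivityByAge:
    def test_planted_rate_increase_detected(self):
        """15% positive old vs 5% young oligodendrocytes, 10 donors/group."""
        rng = np.random.default_rng(11)
        wins = 0
        n_sims = 50
        for _ in range(n_sims):
            rows, pos = [], []
            for grp, rate in (("young", 0.05), ("old", 0.15)):
                for d in range(10):
                    n = 100
                    p = np.clip(rate + rng.normal(0, 0.02), 0.001, 0.999)
                    pos.append(rng.random(n) < p)
                    rows.append(pd.DataFrame(
                        {"donor_id": f"{grp}{d}", "batch": f"B{d % 4}",
                         "sex": "M" if d % 2 else "F", "age_group": grp},
                        index=range(n)))
            obs = pd.concat(rows, ignore_index=True)
            obs.index = obs.index.astype(str)
            from anndata import AnnData

            ad = AnnData(X=np.zeros((len(obs), 1)), obs=obs)
            from senespat.nuclei_stats import masc_test

            res = masc_test(ad, np.concatenate(pos), ("old", "young"),
                            random_effects=("batch",))
            wins += int(res.p < 0.01)
        assert wins >= 45

    def test_degenerate_zero_positives_both_groups(self):
        cols = list(INDIVIDUAL_HALLMARKS)
        n = 60
        scores = pd.DataFrame(np.zeros((n, 7)), columns=cols)
        positivity = pd.DataFrame(
            {c: pd.array([False] * n, dtype="boolean") for c in cols})
        positivity["n_individual_positive"] = 0
        positivity["multi_hallmark"] = False
        nuc = make_nuclei(
            np.ones((n, 2)), [f"d{i % 6}" for i in range(n)],
            ["young"] * (n // 2) + ["old"] * (n // 2),
            batch=[f"B{i % 2}" for i in range(n)],
        )
        positivity.index = nuc.obs_names
        table = positivity_by_age(positivity, nuc,
                                       comparisons=(("old", "young"),))
        assert (table.p == 1.0).all()
        assert (table.z_proportion == 0.0).all()

    def test_specificity_to_planted_hallmark(self):
        """Planting only SASP raises old-vs-young positivity for SASP alone."""
        sen = PlantedSenescence(
            cell_type="Oli",
            fraction_by_group={"young": 0.0, "middle": 0.0, "old": 0.35},
            effect_size=3.0,
            hallmarks=("sasp",),
        )
        cfg = SimConfig(seed=21, n_donors_per_group=4, n_nuclei_per_donor=250,
                        planted_senescence=sen,
                        class_proportions={"Oli": 0.6, "Ast": 0.4})
        nuc, _ = generate_nuclei_dataset(cfg)
        hgs = generate_hallmark_genesets(cfg)
        from senespat.senescence import score_all_hallmarks

        scores = score_all_hallmarks(nuc, hgs, seed=2)
        young = (nuc.obs.age_group == "young").to_numpy()
        old = (nuc.obs.age_group == "old").to_numpy()
        oli = (nuc.obs.broad_class == "Oli").to_numpy()
        cls = nuc.obs.broad_class.to_numpy()
        thr = positivity_thresholds(scores, young, cls)
        pos = classify_positive(scores, thr, cls)
        diffs = {}
        for h in INDIVIDUAL_HALLMARKS:
            col = pos[h].astype("boolean").fillna(False).to_numpy(dtype=bool)
            diffs[h] = col[old & oli].mean() - col[young & oli].mean()
        assert diffs["sasp"] > 0.15
        others = [v for h, v in diffs.items() if h != "sasp"]
        assert max(np.abs(others)) < 0.1


def test_proportion_stat_direction():
    pos = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
    a = np.r_[np.ones(100, bool), np.zeros(100, bool)]
    z, p = proportion_difference_stat(pos, a, ~a)
    assert z > 0 and p < 0.05
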