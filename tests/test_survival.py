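import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathchemo.data_io import ClinicalTable, OmicsMatrix
from pathchemo.simulate import generate_activity_cohort
from pathchemo.survival import (
    cox_model,
    km_logrank,
    loocv_risk,
    random_group_model,
    random_pathway_model,
    roc_auc,
    signature_covariate,
    stratify,
)


def _clin(ids, times, events):
    return ClinicalTable(pd.DataFrame({
        "sample_id": ids, "therapy": "x", "time_to_event": times,
        "event": events, "age": 60.0, "gender": "male", "stage": "II",
        "neoadjuvant": 0,
    }))


def cox_partial_loglik(beta, times, events, x):
    """Brute-force Cox partial log-likelihood (no ties)."""
    ll = 0.0
    for i in np.argsort(times):
        if events[i]:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


class TestStratify:
    def test_separated_blobs_recovered_exactly(self):
        act, clin, truth = generate_activity_cohort(delta=5.0, sigma=0.5, seed=3)
        strat = stratify(act, seed=3)
        assert (strat.group == truth).all()
        assert strat.n_per_group == {"high": 20, "low": 20}

    def test_same_seed_same_labels(self):
        act, _, _ = generate_activity_cohort(seed=5)
        a = stratify(act, seed=9).group
        b = stratify(act, seed=9).group
        assert (a == b).all()

    def test_high_group_has_larger_mean_activity(self):
        act, _, _ = generate_activity_cohort(delta=2.0, sigma=1.0, seed=7)
        strat = stratify(act, seed=7)
        means = act.values.T.mean(axis=1).groupby(strat.group).mean()
        assert means["high"] > means["low"]

    def test_perplexity_too_large_rejected(self):
        act, _, _ = generate_activity_cohort(n_high=5, n_low=5, seed=0)
        with pytest.raises(ValueError, match="perplexity"):
            stratify(act, seed=0, perplexity=9)


class TestKmLogrank:
    def test_identical_curves_give_zero(self):
        ids = [f"s{i}" for i in range(8)]
        clin = _clin(ids, [5, 10, 15, 20] * 2, [1, 1, 0, 0] * 2)
        group = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        stat, p = km_logrank(group, clin)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_o_minus_e(self):
        # A: events day 1, 2; B: censored day 3, 3.
        # t=1: O-E = 1 - 2/4, V = 12/48; t=2: O-E = 1 - 1/3, V = 4/18
        # chi2 = (7/6)^2 / (0.25 + 2/9) = 2.88235...
        ids = ["a1", "a2", "b1", "b2"]
        clin = _clin(ids, [1.0, 2.0, 3.0, 3.0], [1, 1, 0, 0])
        group = pd.Series(["A", "A", "B", "B"], index=ids)
        stat, p = km_logrank(group, clin)
        assert stat == pytest.approx((7 / 6) ** 2 / (0.25 + 2 / 9), rel=1e-10)

    def test_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(20)]
        clin = _clin(ids, rng.exponential(100, 20).round(1),
                     rng.integers(0, 2, 20))
        g = pd.Series(["x"] * 10 + ["y"] * 10, index=ids)
        swapped = g.map({"x": "y", "y": "x"})
        assert km_logrank(g, clin)[1] == pytest.approx(
            km_logrank(swapped, clin)[1]
        )


class TestCoxModel:
    def _toy(self):
        ids = [f"s{i}" for i in range(6)]
        clin = _clin(ids, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1] * 6)
        x = pd.Series([1, 0, 1, 0, 1, 0], index=ids, name="grp")
        return clin, x

    def test_hr_matches_partial_likelihood_grid_search(self):
        clin, x = self._toy()
        fit = cox_model(x.to_frame("grp"), clin, group_col="grp")
        grid = np.linspace(-3, 3, 6001)
        ll = [cox_partial_loglik(b, clin.table["time_to_event"].to_numpy(),
                                 clin.table["event"].to_numpy(),
                                 x.to_numpy()) for b in grid]
        beta_star = grid[int(np.argmax(ll))]
        assert np.log(fit["covariates"]["grp"]["hr"]) == pytest.approx(
            beta_star, abs=1e-3
        )

    def test_hr_inverts_under_label_swap(self):
        clin, x = self._toy()
        a = cox_model(x.to_frame("grp"), clin, group_col="grp")
        b = cox_model((1 - x).to_frame("grp"), clin, group_col="grp")
        assert a["covariates"]["grp"]["hr"] == pytest.approx(
            1 / b["covariates"]["grp"]["hr"], rel=1e-6
        )

    def test_null_covariate_lr_p_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            n = 30
            ids = [f"s{i}" for i in range(n)]
            clin = _clin(ids, rng.exponential(100, n).round(2),
                         np.ones(n, dtype=int))
            x = pd.Series(rng.normal(size=n), index=ids)
            ps.append(cox_model(x.to_frame("x"), clin, group_col="x")["lr_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_covariate_rejected(self):
        clin, x = self._toy()
        with pytest.raises(ValueError, match="constant"):
            cox_model(pd.Series(1.0, index=x.index).to_frame("c"), clin)


class TestSignatureCovariate:
    def test_single_gene_reduces_to_zscore(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(3, 6)),
                            index=["A", "B", "C"],
                            columns=[f"s{i}" for i in range(6)])
        m = OmicsMatrix(vals, "expression")
        score = signature_covariate(m, ["A"])
        z = (vals.loc["A"] - vals.loc["A"].mean()) / vals.loc["A"].std(ddof=1)
        assert np.allclose(score, z)

    def test_no_overlap_is_error(self):
        m = OmicsMatrix(pd.DataFrame(np.ones((1, 3)), index=["A"],
                                     columns=list("abc")), "expression")
        with pytest.raises(ValueError):
            signature_covariate(m, ["ZZZ"])


class TestRandomModels:
    def test_empirical_p_formula(self):
        ids = [f"s{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        clin = _clin(ids, rng.exponential(200, 12).round(1),
                     rng.integers(0, 2, 12))
        g = pd.Series(["high"] * 6 + ["low"] * 6, index=ids)
        res = random_group_model(g, clin, observed_p=0.0, n_draws=50, seed=1)
        assert res.empirical_p == pytest.approx(1 / 51)
        res2 = random_group_model(g, clin, observed_p=1.1, n_draws=50, seed=1)
        assert res2.empirical_p == pytest.approx(1.0)

    def test_exchangeable_null_gives_uniform_empirical_p(self):
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(40):
            ids = [f"s{i}" for i in range(16)]
            clin = _clin(ids, rng.exponential(100, 16).round(2),
                         np.ones(16, dtype=int))
            g = pd.Series(["high"] * 8 + ["low"] * 8, index=ids)
            obs = km_logrank(g, clin)[1]
            res = random_group_model(g, clin, obs, n_draws=60, seed=rep)
            ps.append(res.empirical_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_random_pathway_model_seeded(self, small_cohort):
        from pathchemo.single_sample import zscore_rows

        cohort = small_cohort
        z = zscore_rows(cohort.expression)
        res = random_pathway_model(
            z, cohort.clinical, cohort.collection, observed_p=0.01,
            k=3, n_draws=3, seed=4, n_perm=100,
        )
        res2 = random_pathway_model(
            z, cohort.clinical, cohort.collection, observed_p=0.01,
            k=3, n_draws=3, seed=4, n_perm=100,
        )
        assert np.allclose(res.null_ps, res2.null_ps)
        assert res.n_draws == 3


class TestLoocv:
    def test_perfect_separation_accuracy_one(self):
        act, _, truth = generate_activity_cohort(delta=10.0, sigma=0.5, seed=1)
        y = (truth == "high").astype(int)
        risks, acc = loocv_risk(act, y)
        assert acc == 1.0

    def test_null_labels_accuracy_near_half(self):
        accs = []
        for seed in range(10):
            act, _, _ = generate_activity_cohort(delta=0.0, sigma=1.0,
                                                 n_high=10, n_low=10, seed=seed)
            rng = np.random.default_rng(seed + 100)
            y = pd.Series(rng.integers(0, 2, 20), index=act.sample_ids)
            if y.nunique() < 2:
                continue
            accs.append(loocv_risk(act, y)[1])
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_small_n_rejected(self):
        act, _, truth = generate_activity_cohort(n_high=3, n_low=3, seed=0)
        with pytest.raises(ValueError):
            loocv_risk(act, (truth == "high").astype(int))


class TestRocAuc:
    @pytest.mark.parametrize(
        "labels,scores,expected",
        [
            ([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.1], 1.0),
            ([1, 1, 0, 0], [0.9, 0.4, 0.7, 0.1], 0.75),
            ([1, 1, 0, 0], [0.5, 0.5, 0.5, 0.5], 0.5),
        ],
    )
    def test_concordant_pair_examples(self, labels, scores, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) + 5, labels)
        assert a == pytest.approx(b)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
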