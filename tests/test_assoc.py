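import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from pairscan.assoc import (
    burden_matrix,
    burden_screen,
    cox_interaction,
    group_compare,
    interaction_lm,
    median_split,
)
from pairscan.genome import Region
from pairscan.mutscan import MutationCall
from pairscan.survival import cox_ph, km_curve, logrank_test


class TestBurdenScreen:
    def _fixture(self, rng, n=60, n_genes=30, effect_gene=None, effect=0.0):
        samples = [f"s{i}" for i in range(n)]
        purity = pd.Series(rng.uniform(0.2, 0.9, n), index=samples)
        burden = pd.DataFrame(
            rng.poisson(0.2, size=(n_genes, n)),
            index=[f"g{i}" for i in range(n_genes)], columns=samples,
        )
        y = 5 + 2 * purity.to_numpy() + rng.normal(0, 0.5, n)
        if effect_gene is not None:
            y = y + effect * burden.loc[effect_gene].to_numpy()
        return pd.Series(y, index=samples), burden, purity

    def test_beta_matches_normal_equations(self, rng):
        y, burden, purity = self._fixture(rng)
        res = burden_screen(y, burden, purity)
        gene = res.index[0]
        X = np.column_stack([np.ones(len(y)), purity, burden.loc[gene]])
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert res.loc[gene, "beta"] == pytest.approx(beta[2], abs=1e-10)

    def test_unmutated_gene_not_evaluable(self, rng):
        y, burden, purity = self._fixture(rng)
        burden.loc["g0"] = 0
        res = burden_screen(y, burden, purity)
        assert "g0" not in res.index

    def test_planted_effect_is_top_hit(self, rng):
        y, burden, purity = self._fixture(rng, effect_gene="g7", effect=2.0)
        res = burden_screen(y, burden, purity)
        assert res.index[0] == "g7"

    def test_qq_coordinates(self, rng):
        y, burden, purity = self._fixture(rng)
        res = burden_screen(y, burden, purity)
        assert np.all(np.diff(res["qq_expected"].dropna()) <= 1e-12)
        assert res["qq_observed"].iloc[0] == pytest.approx(
            -np.log10(res["p_value"].iloc[0])
        )


def test_burden_matrix_counts_functional_calls():
    calls = [
        MutationCall("s1", Region("c", 1, 2), "A", "T", "AR", "missense", "T878A", 0.3),
        MutationCall("s1", Region("c", 5, 6), "A", "T", "AR", "stop_gained", "Q10*", 0.3),
        MutationCall("s2", Region("c", 9, 10), "A", "T", "AR", "synonymous", None, 0.3),
        MutationCall("s1", Region("c", 20, 21), "A", "T", None, "noncoding", None, 0.3),
    ]
    mat = burden_matrix(calls, ["s1", "s2"])
    assert mat.loc["AR", "s1"] == 2
    assert mat.loc["AR", "s2"] == 0


class TestGroupCompareAndSplit:
    def test_identical_groups_p_one(self):
        _, p = group_compare([1.0, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert p == pytest.approx(1.0)

    def test_separated_groups_exact(self):
        _, p = group_compare([1.0, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert p == pytest.approx(0.1)

    def test_median_split_even(self):
        g = median_split(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}))
        assert set(g[g == "high"].index) == {"c", "d"}

    def test_median_split_odd_middle_goes_low(self):
        g = median_split(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))
        assert g["b"] == "low"
        assert set(g[g == "high"].index) == {"c"}

    def test_median_split_matches_sort_oracle(self, rng):
        for _ in range(30):
            x = pd.Series(rng.normal(size=int(rng.integers(2, 25))))
            g = median_split(x)
            med = np.median(x)
            assert ((x > med) == (g == "high")).all()

    def test_constant_all_low(self):
        g = median_split(pd.Series([2.0, 2.0, 2.0]))
        assert (g == "low").all()


class TestInteractionLm:
    def test_recovers_additive_construction(self, rng):
        n = 200
        exposure = rng.integers(0, 2, n)
        mut = rng.integers(0, 2, n)
        purity = rng.uniform(0.2, 0.9, n)
        y = 3 - 1.6 * exposure + 2.5 * mut + 0 * exposure * mut + rng.normal(0, 0.8, n)
        out = interaction_lm(pd.Series(y), pd.Series(exposure), pd.Series(mut),
                             pd.Series(purity))
        assert out.loc["exposure", "coef"] == pytest.approx(-1.6, abs=3 * out.loc["exposure", "se"])
        assert out.loc["mut", "coef"] == pytest.approx(2.5, abs=3 * out.loc["mut", "se"])

    def test_null_interaction_p_uniform(self, rng):
        ps = []
        for _ in range(150):
            n = 80
            exposure = rng.integers(0, 2, n)
            mut = rng.integers(0, 2, n)
            y = 1 + exposure - mut + rng.normal(0, 1, n)
            out = interaction_lm(pd.Series(y), pd.Series(exposure),
                                 pd.Series(mut), pd.Series(rng.uniform(0, 1, n)))
            ps.append(out.loc["interaction", "p_value"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_single_level_exposure_degenerates(self, rng):
        n = 30
        out = interaction_lm(
            pd.Series(rng.normal(size=n)), pd.Series(np.ones(n)),
            pd.Series(rng.integers(0, 2, n)), pd.Series(rng.uniform(0, 1, n)),
        )
        assert "interaction" not in out.index
        assert any("single-level" in note for note in out.attrs["notes"])


def naive_efron_negll(beta, t, e, X):
    ll = 0.0
    eta = X @ beta
    for tt in np.unique(t[e.astype(bool)]):
        D = np.flatnonzero((t == tt) & (e == 1))
        R = np.flatnonzero(t >= tt)
        d = len(D)
        ll += eta[D].sum()
        sR = np.exp(eta[R]).sum()
        sD = np.exp(eta[D]).sum()
        for r in range(d):
            ll -= np.log(sR - (r / d) * sD)
    return -ll


class TestSurvival:
    def test_km_matches_product_limit_hand_computation(self):
        # classic small fixture: times 1,2+,3,4,4,5+ (events unless +)
        time = np.array([1.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        event = np.array([1, 0, 1, 1, 1, 0])
        km = km_curve(time, event)
        # S(1)=5/6; S(3)=5/6*3/4; S(4)=5/6*3/4*1/3
        assert km.set_index("time")["survival"].to_dict() == pytest.approx(
            {1.0: 5 / 6, 3.0: 5 / 6 * 3 / 4, 4.0: 5 / 6 * 3 / 4 * 1 / 3}
        )

    def test_no_events_flat_curve_and_cox_raises(self):
        km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.empty  # no drops: survival stays at 1
        with pytest.raises(ValueError, match="no events"):
            cox_ph([1.0, 2.0], [0, 0], np.ones((2, 1)))

    def test_cox_matches_naive_likelihood_maximizer(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 25))
            X = rng.normal(size=(n, 2))
            t = np.round(rng.exponential(1 / np.exp(0.5 * X[:, 0])), 1) + 0.1
            e = (rng.random(n) < 0.7).astype(int)
            if e.sum() < 2:
                continue
            res = cox_ph(t, e, X)
            opt = minimize(naive_efron_negll, np.zeros(2), args=(t, e, X),
                           method="BFGS", options={"gtol": 1e-10})
            assert np.allclose(res.coef, opt.x, atol=1e-5)

    def test_cox_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 120
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1 / np.exp(0.4 * X[:, 0] - 0.6 * X[:, 1]))
        e = (rng.random(n) < 0.8).astype(int)
        res = cox_ph(t, e, X)
        df = pd.DataFrame({"t": t, "e": e, "x0": X[:, 0], "x1": X[:, 1]})
        cf = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(res.coef, cf.params_.values, atol=1e-3)

    def test_separation_flagged_and_capped(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 1, 1, 0, 0, 0])[:, None]  # perfect separation
        res = cox_ph(t, e, x)
        assert res.monotone_flag
        assert np.abs(res.coef[0]) <= 15.0

    def test_logrank_null_and_separated(self, rng):
        t = rng.exponential(10, 40)
        e = np.ones(40, int)
        g = np.repeat([0, 1], 20)
        chi2, p = logrank_test(t, e, g)
        assert p > 0.001  # same distribution: should rarely be extreme
        t2 = np.concatenate([rng.exponential(2, 20), rng.exponential(40, 20)])
        _, p2 = logrank_test(t2, e, g)
        assert p2 < 0.001


class TestCoxInteraction:
    def _surv(self, rng, n=160, interaction=1.0):
        group = np.where(rng.random(n) < 0.5, "low", "high")
        treated = rng.random(n) < 0.5
        lam = 0.05 * np.exp(
            -0.8 * treated + 0.2 * (group == "low")
            + interaction * treated * (group == "low")
        )
        t = rng.exponential(1 / lam)
        c = rng.uniform(5, 80, n)
        surv = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "time_months": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "treatment_after_biopsy": np.where(treated, "ARSI", "other"),
        })
        return surv, pd.Series(group, index=surv["sample_id"])

    def test_interaction_recovered_within_3se(self, rng):
        surv, group = self._surv(rng, n=500, interaction=1.0)
        res = cox_interaction(surv, group)
        i = res.cox.names.index("group_low:treated")
        assert res.cox.coef[i] == pytest.approx(1.0, abs=3 * res.cox.se[i])
        assert set(res.km_curves) <= {"high_treated", "high_other",
                                      "low_treated", "low_other"}

    def test_missing_group_labels_raise(self, rng):
        surv, group = self._surv(rng, n=20)
        with pytest.raises(ValueError, match="missing"):
            cox_interaction(surv, group.iloc[:5])
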