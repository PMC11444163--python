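import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from pairscan.dge import (
    batch_center,
    design_matrix,
    nb_wald,
    plot_transform,
    size_factors,
    variance_change_test,
)
from pairscan.simulate import CohortConfig, ExpressionSpec, nb_counts, simulate_cohort


def make_samples(n_pairs, purity=None, batch=None):
    rows = []
    for i in range(n_pairs):
        for tp in ("pre", "post"):
            rows.append({
                "sample_id": f"P{i}-{tp}", "patient_id": f"P{i}", "timepoint": tp,
                "purity": 0.5 if purity is None else purity[len(rows)],
                "batch": "b0" if batch is None else batch[len(rows)],
                "arsi_exposed": int(tp == "post"),
            })
    return pd.DataFrame(rows)


class TestSizeFactors:
    def test_doubled_column(self, rng):
        a = rng.poisson(50, size=(30, 1)).astype(float) + 1
        mat = np.hstack([a, 2 * a])
        f = size_factors(mat)
        assert f[1] / f[0] == pytest.approx(2.0, rel=1e-12)

    def test_identical_columns_unit_factors(self, rng):
        col = rng.poisson(20, size=40).astype(float) + 1
        mat = np.tile(col[:, None], (1, 5))
        assert np.allclose(size_factors(mat), 1.0)

    def test_matches_median_of_ratios_formula(self, rng):
        mat = rng.poisson(30, size=(100, 6)).astype(float) + 1
        f = size_factors(mat)
        logref = np.log(mat).mean(axis=1)
        expected = np.exp(np.median(np.log(mat) - logref[:, None], axis=0))
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f, expected, atol=1e-12)

    def test_fallback_warns_when_no_common_positive_gene(self, rng):
        mat = rng.poisson(10, size=(20, 3)).astype(float)
        mat[np.arange(20), np.arange(20) % 3] = 0  # every gene has a zero
        with pytest.warns(RuntimeWarning, match="positive-subset"):
            f = size_factors(mat)
        assert np.all(f > 0)


class TestDesignMatrix:
    def test_paired_columns_and_collinear_batch_drop(self):
        samples = make_samples(3, batch=["b0", "b0", "b1", "b1", "b0", "b0"])
        # batch is constant within patient here only for some; add a case where
        # batch == patient partition to force a drop
        samples2 = make_samples(2, batch=["b0", "b0", "b1", "b1"])
        X, names, ti, dropped = design_matrix(samples2, mode="paired")
        assert "batch_b1" in dropped  # aliased with patient indicator
        assert names[ti] == "timepoint_post"
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_unpaired_has_no_patient_columns(self):
        X, names, _, _ = design_matrix(make_samples(3), mode="unpaired")
        assert not any(n.startswith("patient_") for n in names)


class TestNbWald:
    def test_poisson_special_case_matches_mle_oracle(self, rng):
        """With dispersion ~ 0 the IRLS fit equals the Poisson GLM MLE found
        by an independent numerical optimizer."""
        n = 12
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.uniform(0, 1, n)])
        beta_true = np.array([2.0, -0.7, 0.5])
        y = rng.poisson(np.exp(X @ beta_true)).astype(float)

        def negll(b):
            eta = X @ b
            return -(y @ eta - np.exp(eta).sum())

        opt = minimize(negll, np.zeros(3), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 500})
        from pairscan.dge import _irls

        beta, _, ok = _irls(y, X, np.zeros(n), 1e-8)
        assert ok
        assert np.allclose(beta, opt.x, atol=1e-6)

    def test_spiked_gene_recovered(self):
        cfg = CohortConfig(n_patients=20,
                           expression=ExpressionSpec(n_genes=60, dosage_genes=()))
        cohort = simulate_cohort(cfg, seed=5, components=("meta", "expression"))
        res = nb_wald(cohort.counts, cohort.meta, mode="paired")
        row = res.loc["SSTR1"]
        assert row["log2_fc"] < -0.5
        assert row["q_value"] < 0.05

    def test_all_zero_gene_excluded(self):
        samples = make_samples(6)
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(30, size=(20, 12)),
                              index=[f"g{i}" for i in range(20)],
                              columns=samples["sample_id"])
        counts.iloc[3] = 0
        res = nb_wald(counts, samples, covariates=())
        assert res.loc["g3", "excluded"]
        assert np.isnan(res.loc["g3", "p_value"])
        assert res["q_value"].dropna().min() >= res["p_value"].dropna().min()

    def test_null_gene_p_uniform_across_simulations(self):
        """A designated null gene, 30 pairs, repeated simulations (with a
        background of genes so normalization is non-degenerate): the
        two-sided Wald p of the focal gene is uniform (KS at alpha=0.01)."""
        samples = make_samples(30)
        rng = np.random.default_rng(42)
        pvals = []
        n_bg = 40
        base = 2.0 ** rng.uniform(4, 9, n_bg + 1)
        patient_effect = rng.normal(0, 0.3, size=(n_bg + 1, 30)).repeat(2, axis=1)
        for _ in range(200):
            mu = base[:, None] * np.exp(patient_effect)
            y = nb_counts(rng, mu, 0.1).astype(float)
            counts = pd.DataFrame(y, index=[f"g{i}" for i in range(n_bg + 1)],
                                  columns=samples["sample_id"])
            res = nb_wald(counts, samples, covariates=())
            pvals.append(res.loc["g0", "p_value"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_patient_confounder_absorbed_in_paired_mode(self):
        """Huge patient effects do not inflate null rejections when patient
        indicators are in the design."""
        samples = make_samples(20)
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(150)]
        patient_effect = rng.normal(0, 1.5, size=(150, 20)).repeat(2, axis=1)
        mu = 80 * np.exp(patient_effect)
        counts = pd.DataFrame(nb_counts(rng, mu, 0.1), index=genes,
                              columns=samples["sample_id"])
        res = nb_wald(counts, samples, covariates=())
        rate = (res["p_value"].dropna() < 0.05).mean()
        assert rate < 0.12  # binomial 99.9% upper bound around 0.05 for n=150


class TestVarianceChange:
    def test_boundary_f_equals_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        res = variance_change_test(vals, vals.copy(), log=False)
        assert res.f_statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_doubled_sd_median_f_near_four(self, rng):
        fs = [
            variance_change_test(rng.normal(0, 1, 30), rng.normal(0, 2, 30),
                                 log=False).f_statistic
            for _ in range(400)
        ]
        assert np.median(fs) == pytest.approx(4.0, rel=0.25)

    def test_null_p_uniform(self, rng):
        ps = [
            variance_change_test(rng.normal(0, 1, 25), rng.normal(0, 1, 25),
                                 log=False).p_value
            for _ in range(300)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_flagged(self):
        res = variance_change_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], log=False)
        assert res.flagged_infinite and np.isinf(res.f_statistic)


class TestBatchCenter:
    def _frame(self, mat, batches):
        return (
            pd.DataFrame(mat, columns=[f"s{i}" for i in range(mat.shape[1])]),
            batches,
        )

    def test_single_batch_identity(self, rng):
        df, batches = self._frame(rng.normal(5, 1, size=(10, 6)), ["b"] * 6)
        out = batch_center(df, batches)
        assert np.allclose(out.to_numpy(), df.to_numpy())

    def test_constant_offset_removed(self, rng):
        base = rng.normal(5, 1, size=(10, 4))
        mat = np.hstack([base, base + 3.0])
        df, batches = self._frame(mat, ["a"] * 4 + ["b"] * 4)
        out = batch_center(df, batches).to_numpy()
        assert np.allclose(out[:, :4] - out[:, 4:], 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        df, batches = self._frame(rng.normal(0, 2, size=(15, 9)),
                                  ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        once = batch_center(df, batches)
        twice = batch_center(once, batches)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_singleton_batch_warns(self, rng):
        df, batches = self._frame(rng.normal(0, 1, size=(5, 3)), ["a", "a", "b"])
        with pytest.warns(RuntimeWarning, match="singleton"):
            batch_center(df, batches)


class TestPlotTransform:
    def test_examples(self):
        counts = pd.DataFrame({"s1": [0.0, 3.0]}, index=["g1", "g2"])
        out = plot_transform(counts, np.array([1.0]))
        assert out.loc["g1", "s1"] == 0.0
        assert out.loc["g2", "s1"] == pytest.approx(2.0)

    def test_monotone(self, rng):
        counts = pd.DataFrame({"s": np.sort(rng.integers(0, 1000, 50))})
        out = plot_transform(counts, np.array([1.7]))
        assert (np.diff(out["s"]) >= 0).all()
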