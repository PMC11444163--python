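import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pairscan.scores import (
    GeneSet,
    ar_ne_scores,
    change_pca_outliers,
    isoform_fractions,
    ssgsea,
    ssgsea_matrix,
    subtype_scores,
)


def brute_force_ssgsea(expr: pd.Series, members: set, tau: float) -> float:
    """Independent literal implementation of the weighted-ECDF statistic."""
    vals = expr.to_numpy(dtype=float)
    genes = list(expr.index)
    ranks = sps.rankdata(vals)
    order = sorted(range(len(genes)), key=lambda i: (-vals[i], i))
    total_in = sum(ranks[i] ** tau for i in order if genes[i] in members)
    n_out = len(genes) - len(members & set(genes))
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in order:
        if genes[i] in members:
            cum_in += ranks[i] ** tau
        else:
            cum_out += 1
        score += cum_in / total_in - cum_out / n_out
    return score


class TestSsgsea:
    def test_hand_computed_toy(self):
        # 5 genes ranked A>B>C>D>E, set = {A, B}, tau = 0:
        # positions: in,in,out,out,out -> (1/2-0)+(1-0)+(1-1/3)+(1-2/3)+(1-1)=2.5
        expr = pd.Series([5.0, 4, 3, 2, 1], index=list("ABCDE"))
        assert ssgsea(expr, GeneSet("top", ("A", "B")), tau=0.0) == pytest.approx(2.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            genes = [f"g{i}" for i in range(n)]
            expr = pd.Series(rng.normal(size=n), index=genes)
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(genes, size=k, replace=False))
            tau = float(rng.choice([0.0, 0.25, 1.0]))
            mine = ssgsea(expr, GeneSet("s", tuple(sorted(members))), tau=tau)
            assert mine == pytest.approx(
                brute_force_ssgsea(expr, members, tau), abs=1e-9
            )

    def test_invariant_under_monotone_transform(self, rng):
        genes = [f"g{i}" for i in range(30)]
        expr = pd.Series(rng.normal(size=30), index=genes)
        gs = GeneSet("s", tuple(genes[:7]))
        a = ssgsea(expr, gs)
        b = ssgsea(np.exp(expr * 3) + 2, gs)
        assert a == pytest.approx(b, abs=1e-12)

    def test_antisymmetric_at_tau_zero(self):
        expr = pd.Series(np.arange(10, 0, -1, dtype=float),
                         index=[f"g{i}" for i in range(10)])
        top = GeneSet("top", tuple(f"g{i}" for i in range(3)))
        bottom = GeneSet("bot", tuple(f"g{i}" for i in range(7, 10)))
        assert ssgsea(expr, bottom, tau=0.0) == pytest.approx(
            -ssgsea(expr, top, tau=0.0)
        )

    def test_error_cases(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="no genes"):
            ssgsea(expr, GeneSet("s", ("x",)))
        with pytest.raises(ValueError, match="empty out-set"):
            ssgsea(expr, GeneSet("s", ("a", "b")))

    def test_matrix_normalization_shared_scale(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 4)),
                            index=[f"g{i}" for i in range(20)],
                            columns=list("wxyz"))
        sets = [GeneSet("a", ("g0", "g1", "g2")), GeneSet("b", ("g5", "g6"))]
        raw = ssgsea_matrix(expr, sets)
        norm = ssgsea_matrix(expr, sets, normalize=True)
        span = raw.to_numpy().max() - raw.to_numpy().min()
        assert np.allclose(norm.to_numpy(), raw.to_numpy() / span)


class TestArNeScores:
    def _matrix(self, rng, genes, n_samples=8):
        return pd.DataFrame(rng.normal(size=(len(genes), n_samples)),
                            index=genes,
                            columns=[f"s{i}" for i in range(n_samples)])

    def test_template_match_scores_one(self, rng):
        genes = [f"g{i}" for i in range(6)]
        dirs = (1, 1, -1, 1, -1, -1)
        expr = self._matrix(rng, genes)
        # construct one sample whose z-scores equal the template exactly
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        target = expr.mean(axis=1) + expr.std(axis=1, ddof=0) * np.asarray(dirs)
        expr2 = expr.copy()
        expr2["probe"] = target
        gs = GeneSet("NE", tuple(genes), dirs)
        scores = ar_ne_scores(expr2, gs, gs)
        # probe sample: z-profile proportional to template -> score near 1
        assert scores.loc["probe", "ne_score"] > 0.85

    def test_negated_template_negates_score(self, rng):
        genes = [f"g{i}" for i in range(5)]
        expr = self._matrix(rng, genes)
        up = GeneSet("A", tuple(genes), (1, 1, 1, -1, -1))
        down = GeneSet("B", tuple(genes), (-1, -1, -1, 1, 1))
        a = ar_ne_scores(expr, up, up)["ar_score"]
        b = ar_ne_scores(expr, down, down)["ar_score"]
        assert np.allclose(a, -b)

    def test_bounded_and_affine_invariant(self, rng):
        genes = [f"g{i}" for i in range(8)]
        expr = self._matrix(rng, genes, 10)
        gs = GeneSet("AR", tuple(genes), tuple(rng.choice([-1, 1], 8)))
        s1 = ar_ne_scores(expr, gs, gs)
        assert s1["ar_score"].abs().max() <= 1.0 + 1e-12
        rescaled = expr.mul(rng.uniform(0.5, 3, size=8), axis=0).add(
            rng.normal(size=8), axis=0)
        s2 = ar_ne_scores(rescaled, gs, gs)
        assert np.allclose(s1["ar_score"], s2["ar_score"], atol=1e-9)

    def test_ne_high_threshold(self, rng):
        genes = [f"g{i}" for i in range(5)]
        expr = self._matrix(rng, genes)
        gs = GeneSet("NE", tuple(genes), (1, -1, 1, -1, 1))
        out = ar_ne_scores(expr, gs, gs, ne_high_threshold=0.4)
        assert out["ne_high"].equals(out["ne_score"] > 0.4)

    def test_too_few_genes_raises(self, rng):
        expr = self._matrix(rng, ["a", "b", "c"])
        with pytest.raises(ValueError, match="fewer than 3"):
            ar_ne_scores(expr, GeneSet("s", ("a", "x", "y")),
                         GeneSet("s2", ("a", "b", "c")))


class TestSubtypeAndChangePca:
    def test_planted_converter_is_outlier(self, rng):
        idx = [f"pair{i}" for i in range(20)]
        deltas = pd.DataFrame(rng.normal(0, 1, size=(20, 4)), index=idx,
                              columns=["AR", "NEPC", "Wnt", "SCL"])
        deltas.iloc[0] = [8.0, -8.0, 0.5, 0.2]
        res = change_pca_outliers(deltas)
        assert "pair0" in res.outliers

    def test_all_zero_deltas_no_outliers(self):
        deltas = pd.DataFrame(np.zeros((6, 4)),
                              columns=["AR", "NEPC", "Wnt", "SCL"])
        res = change_pca_outliers(deltas)
        assert res.outliers == []
        assert res.dropped_columns == ["AR", "NEPC", "Wnt", "SCL"]

    def test_pca_projection_roundtrip_identity(self, rng):
        deltas = pd.DataFrame(rng.normal(size=(12, 4)))
        z = ((deltas - deltas.mean()) / deltas.std(ddof=0)).to_numpy()
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        back = (u * s) @ vt
        assert np.allclose(back, z, atol=1e-9)

    def test_subtype_scores_are_mean_z(self, rng):
        genes = ["t1", "t2", "t3", "x1"]
        expr = pd.DataFrame(rng.normal(size=(4, 6)), index=genes,
                            columns=[f"s{i}" for i in range(6)])
        gs = GeneSet("CRPC-AR", ("t1", "t2", "t3"))
        out = subtype_scores(expr, [gs])
        z = expr.loc[["t1", "t2", "t3"]]
        z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1, ddof=0), axis=0)
        assert np.allclose(out["CRPC-AR"], z.mean(axis=0))


class TestIsoformFractions:
    def _table(self, v7, fl, samples=("s1",)):
        return pd.DataFrame({
            "transcript_id": ["AR-V7", "AR-FL"],
            "gene": ["AR", "AR"],
            **{s: [v7[i], fl[i]] for i, s in enumerate(samples)},
        })

    def test_simple_proportions(self):
        out = isoform_fractions(self._table([25.0], [75.0]), "AR")
        assert out.loc["AR-V7", "s1"] == pytest.approx(0.25)
        assert out.loc["AR-FL", "s1"] == pytest.approx(0.75)

    def test_single_transcript_fraction_one(self):
        table = pd.DataFrame({"transcript_id": ["T1"], "gene": ["G"], "s1": [42.0]})
        out = isoform_fractions(table, "G")
        assert out.loc["T1", "s1"] == 1.0

    def test_all_zero_undefined_flagged(self):
        out = isoform_fractions(self._table([0.0], [0.0]), "AR")
        assert np.isnan(out["s1"]).all()
        assert out.attrs["defined"]["s1"] is np.False_

    def test_converter_delta(self):
        # a pair moving from a 0.1% to a 60.7% variant fraction
        table = self._table([0.1, 60.7], [99.9, 39.3], samples=("pre", "post"))
        out = isoform_fractions(table, "AR")
        delta = out.loc["AR-V7", "post"] - out.loc["AR-V7", "pre"]
        assert delta == pytest.approx(0.606, abs=1e-9)

    def test_fractions_sum_to_one_where_defined(self, rng):
        table = pd.DataFrame({
            "transcript_id": [f"T{i}" for i in range(4)],
            "gene": ["G"] * 4,
            **{f"s{j}": rng.uniform(0, 10, 4) for j in range(5)},
        })
        out = isoform_fractions(table, "G")
        assert np.allclose(out.sum(axis=0), 1.0)

    def test_missing_gene_raises(self):
        with pytest.raises(ValueError, match="no transcripts"):
            isoform_fractions(self._table([1.0], [1.0]), "TP53")
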