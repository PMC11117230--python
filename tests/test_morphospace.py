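import numpy as np
import pandas as pd
import pytest

import biphasic as bp
from biphasic.morphospace import term_matrix


class TestPca:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        X = pd.DataFrame(np.outer(base, [1.0, -2.0, 0.5]))
        res = bp.pca(X)
        assert res.var_explained[0] == pytest.approx(1.0)
        assert res.scores.shape[1] == 1

    def test_reconstruction_from_all_pcs(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 8)))
        res = bp.pca(X)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.center.to_numpy()
        np.testing.assert_allclose(recon, X.to_numpy(), atol=1e-9)

    def test_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 8)))
        res = bp.pca(X)
        cov = np.cov(X.to_numpy(), rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        np.testing.assert_allclose(
            res.scores.var(axis=0, ddof=1).to_numpy(), evals, rtol=1e-9
        )
        np.testing.assert_allclose(
            res.var_explained, evals / evals.sum(), rtol=1e-9
        )
        for j in range(8):
            v = evecs[:, order[j]]
            got = res.loadings.iloc[:, j].to_numpy()
            assert abs(abs(v @ got) - 1.0) < 1e-9  # same axis up to sign

    def test_invariants(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(15, 6)))
        res = bp.pca(X)
        assert res.var_explained.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        # sign convention: dominant loading positive
        for j in range(L.shape[1]):
            assert L[np.abs(L[:, j]).argmax(), j] > 0

    def test_total_variance_matches_procrustes_variance(self, template):
        rng = np.random.default_rng(4)
        configs = np.stack(
            [template + rng.normal(0, 0.02, template.shape) for _ in range(12)]
        )
        aligned = bp.gpa(configs)
        res = bp.pca(aligned.coords)
        ssq = res.scores.to_numpy()
        total_var = (ssq**2).sum() / len(ssq)  # divisor n
        assert total_var == pytest.approx(
            bp.procrustes_variance(aligned.coords), abs=1e-12
        )


def _design(n, rng, levels=("x", "y", "z")):
    return pd.DataFrame(
        {
            "g": rng.choice(levels, n),
            "size": rng.normal(size=n),
        }
    )


class TestProcrustesAnova:
    def test_ss_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 20
        design = _design(n, rng)
        Y = rng.normal(size=(n, 4))
        table = bp.procrustes_anova(Y, design, ["size", "g"], nperm=99, seed=0)

        # oracle: explicit design matrices + lstsq residual cross-products
        def rss(X):
            beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
            r = Y - X @ beta
            return (r**2).sum()

        ones = np.ones((n, 1))
        Xs = np.hstack([ones, design[["size"]].to_numpy()])
        Xg = np.hstack([Xs, pd.get_dummies(design["g"], drop_first=True).to_numpy()])
        assert table["size"]["SS"] == pytest.approx(rss(ones) - rss(Xs), abs=1e-8)
        assert table["g"]["SS"] == pytest.approx(rss(Xs) - rss(Xg), abs=1e-8)
        assert table["Residuals"]["SS"] == pytest.approx(rss(Xg), abs=1e-8)
        assert table["Total"]["SS"] == pytest.approx(rss(ones), abs=1e-8)

    def test_exact_decomposition_and_rsq(self):
        rng = np.random.default_rng(6)
        n = 30
        design = _design(n, rng)
        Y = rng.normal(size=(n, 6))
        t = bp.procrustes_anova(Y, design, ["g", "size"], nperm=99, seed=1).table
        terms_ss = t.loc[["g", "size"], "SS"].sum() + t.loc["Residuals", "SS"]
        assert terms_ss == pytest.approx(t.loc["Total", "SS"], rel=1e-9)
        assert t.loc[["g", "size", "Residuals"], "Rsq"].sum() == pytest.approx(1.0)

    def test_perfect_fit(self):
        rng = np.random.default_rng(7)
        g = np.repeat(["a", "b", "c"], 5)
        means = {"a": [0.0, 1.0], "b": [3.0, -1.0], "c": [-2.0, 2.0]}
        Y = np.array([means[x] for x in g])
        design = pd.DataFrame({"g": g})
        nperm = 199
        table = bp.procrustes_anova(Y, design, ["g"], nperm=nperm, seed=2)
        assert table["g"]["Rsq"] == pytest.approx(1.0)
        assert table["g"]["p"] == pytest.approx(1 / (nperm + 1))

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        design = _design(25, rng)
        Y = rng.normal(size=(25, 3))
        a = bp.procrustes_anova(Y, design, ["g"], nperm=199, seed=42).table
        b = bp.procrustes_anova(Y, design, ["g"], nperm=199, seed=42).table
        pd.testing.assert_frame_equal(a, b)

    def test_constant_response_rejected(self):
        design = _design(10, np.random.default_rng(9))
        with pytest.raises(ValueError, match="total SS"):
            bp.procrustes_anova(np.ones((10, 2)), design, ["g"], nperm=99)

    def test_confounded_term_rejected(self):
        rng = np.random.default_rng(10)
        design = pd.DataFrame({"g": ["a", "b"] * 5, "h": ["a", "b"] * 5})
        Y = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="confounded|estimable"):
            bp.procrustes_anova(Y, design, ["g", "h"], nperm=99)

    def test_interaction_term_matrix(self):
        design = pd.DataFrame({"g": ["a", "b", "a"], "size": [1.0, 2.0, 3.0]})
        m = term_matrix(design, "size:g")
        np.testing.assert_allclose(m[:, 0], [0.0, 2.0, 0.0])


class TestAllometry:
    def test_noiseless_linear_data(self):
        rng = np.random.default_rng(11)
        n = 25
        size = pd.Series(rng.uniform(1, 3, n), index=[f"s{i}" for i in range(n)])
        b = rng.normal(size=6)
        Y = pd.DataFrame(np.outer(size, b), index=size.index)
        res = bp.allometry_regression(Y, size, nperm=199, seed=0)
        assert res.anova["size"]["Rsq"] == pytest.approx(1.0)
        rho = pd.Series(res.regression_score).corr(size, method="spearman")
        assert abs(rho) == pytest.approx(1.0)

    def test_interaction_matches_plain_anova(self):
        rng = np.random.default_rng(12)
        n = 30
        idx = [f"s{i}" for i in range(n)]
        size = pd.Series(rng.normal(size=n), index=idx)
        groups = pd.Series(rng.choice(["u", "v"], n), index=idx)
        Y = pd.DataFrame(rng.normal(size=(n, 5)), index=idx)
        res = bp.allometry_regression(Y, size, groups=groups, nperm=199, seed=3)
        design = pd.DataFrame({"size": size, "group": groups.astype(str)})
        direct = bp.procrustes_anova(
            Y.to_numpy(), design, ["size", "group", "size:group"], nperm=199, seed=3
        )
        for term in ("size", "group", "size:group"):
            assert res.anova[term]["Rsq"] == pytest.approx(
                direct[term]["Rsq"], abs=1e-10
            )

    def test_null_slopes_give_uniformish_p(self):
        rng = np.random.default_rng(13)
        n = 40
        idx = [f"s{i}" for i in range(n)]
        ps = []
        for rep in range(40):
            size = pd.Series(rng.normal(size=n), index=idx)
            groups = pd.Series(["g1"] * 20 + ["g2"] * 20, index=idx)
            Y = pd.DataFrame(rng.normal(size=(n, 4)), index=idx)
            res = bp.allometry_regression(Y, size, groups=groups, nperm=99, seed=rep)
            ps.extend(res.group_stats["p"].tolist())
        assert 0.30 < np.mean(np.asarray(ps) < 0.5) < 0.70

    def test_small_group_skipped(self):
        rng = np.random.default_rng(14)
        idx = [f"s{i}" for i in range(10)]
        Y = pd.DataFrame(rng.normal(size=(10, 3)), index=idx)
        size = pd.Series(rng.normal(size=10), index=idx)
        groups = pd.Series(["big"] * 8 + ["tiny"] * 2, index=idx)
        res = bp.allometry_regression(Y, size, groups=groups, nperm=99, seed=0)
        assert "tiny" not in res.group_stats.index
        assert "big" in res.group_stats.index
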